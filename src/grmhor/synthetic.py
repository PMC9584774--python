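"""Synthetic tandem arrays of 3mer HOR copies with ground truth.

Emulates the statistical regime of the human NBPF 3mer HOR: three ~1.6-kb
monomer types (m1, m2, m3) that diverge from each other by ~18%, concatenated
into a ~4.77-kb HOR unit; tandem arrays of HOR copies that diverge from the
unit by ~0.8% each (hence ~1.6% from each other); four arrays of 19, 13, 11
and 7 copies embedded in random flanking sequence.  Every generated position
is recorded in a truth annotation so detection and annotation can be scored
exactly.

The mutation model is deliberately simple: substitutions uniform over the
three alternative bases, single-base indels with equal insertion/deletion
probability.  It reproduces the divergence statistics and the ~±3% monomer
length spread, not the actual mutational history of the repeat family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .hor import MonomerConsensusSet, pairwise_divergence
from .sequence_io import Interval, NamedSequence

__all__ = [
    "HORSimParams",
    "TruthAnnotation",
    "make_monomer_consensuses",
    "simulate_hor_array",
    "simulate_genome",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HORSimParams:
    """Generator parameters; the defaults are the regime being emulated."""

    monomer_lengths: tuple[int, ...] = (1623, 1593, 1554)
    intra_divergence_target: float = 18.0  # pct between monomer consensuses
    copy_substitution_rate: float = 0.008  # per base, per copy
    copy_indel_rate: float = 0.0005  # per base, per copy
    array_sizes: tuple[int, ...] = (19, 13, 11, 7)
    inter_array_gap: int = 5_000
    flank_length: int = 10_000
    gc_content: float = 0.41
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.copy_substitution_rate, self.copy_indel_rate):
            if not (0 <= r < 0.5):
                raise ValueError("mutation rates must be in [0, 0.5)")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class TruthAnnotation:
    """Ground-truth intervals of a simulated sequence (0-based half-open)."""

    monomers: list[Interval] = field(default_factory=list)  # name = label
    copies: list[Interval] = field(default_factory=list)  # name = array:copy
    arrays: list[Interval] = field(default_factory=list)
    substitutions_per_copy: list[int] = field(default_factory=list)

    def shifted(self, offset: int) -> "TruthAnnotation":
        def sh(ivs):
            return [
                Interval(iv.seq_id, iv.start + offset, iv.end + offset,
                         iv.strand, iv.name)
                for iv in ivs
            ]

        return TruthAnnotation(
            monomers=sh(self.monomers),
            copies=sh(self.copies),
            arrays=sh(self.arrays),
            substitutions_per_copy=list(self.substitutions_per_copy),
        )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each base independently with the given probability, choosing
    uniformly among the three alternatives.  Returns (sequence, #subs)."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        alts = BASES[BASES != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return arr.tobytes().decode(), int(idx.size)


def _indel(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply single-base insertions/deletions, each with probability rate/2
    per position."""
    if rate <= 0:
        return seq
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        if r < rate:
            out.append(BASES[rng.integers(4)].decode())  # insertion before ch
        out.append(ch)
    return "".join(out)


def _nested_deletion_sets(lengths: tuple[int, ...], L_max: int,
                          rng: np.random.Generator) -> list[np.ndarray]:
    """Deletion positions bringing an L_max ancestor down to each length.

    The sets are nested (a shorter monomer's deletions contain a longer
    one's), which keeps the indel component of pairwise divergence to the
    difference of lengths instead of their sum and thus keeps the three
    pairwise divergences close together.
    """
    order = np.argsort([L_max - L for L in lengths])[::-1]  # most deletions first
    biggest = rng.permutation(L_max)[: L_max - min(lengths)]
    sets: list[np.ndarray | None] = [None] * len(lengths)
    for rank, i in enumerate(order):
        ndel = L_max - lengths[i]
        sets[i] = np.sort(biggest[:ndel])
    return sets  # type: ignore[return-value]


def _delete_positions(seq: str, positions: np.ndarray) -> str:
    if positions.size == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    mask = np.ones(arr.size, dtype=bool)
    mask[positions] = False
    return arr[mask].tobytes().decode()


def make_monomer_consensuses(
    params: HORSimParams, rng: np.random.Generator, max_retries: int = 50
) -> MonomerConsensusSet:
    """Derive monomer consensuses from a common ancestor so that realized
    pairwise divergences land within +-2 points of the target.

    The substitution rate applied per monomer is tuned iteratively against
    the measured pairwise divergence (the measurement, not the nominal rate,
    is what downstream modules see).  Length differences are realized by
    nested deletion sets from the ancestor, so the indel component of the
    pairwise divergence is the length difference of the pair.
    """
    import itertools

    target = params.intra_divergence_target
    lengths = params.monomer_lengths
    labels = [f"m{i + 1}" for i in range(len(lengths))]
    L_max = max(lengths)
    ancestor = _random_seq(rng, L_max, params.gc_content)
    del_sets = _nested_deletion_sets(lengths, L_max, rng)
    if target <= 0:
        return MonomerConsensusSet(
            monomers=[(lab, _delete_positions(ancestor, ds))
                      for lab, ds in zip(labels, del_sets)]
        )
    # per-branch rate start: pairwise divergence accumulates on two branches
    rate = target / 200.0
    for _ in range(max_retries):
        monomers = []
        for lab, ds in zip(labels, del_sets):
            mutated, _ = _substitute(ancestor, rate, rng)
            monomers.append((lab, _delete_positions(mutated, ds)))
        divs = [
            pairwise_divergence(a, b)
            for (_, a), (_, b) in itertools.combinations(monomers, 2)
        ]
        mean = sum(divs) / len(divs)
        if abs(mean - target) <= 0.5 and all(abs(d - target) <= 2.0 for d in divs):
            return MonomerConsensusSet(monomers=monomers)
        rate = min(0.49, max(1e-4, rate * target / mean))
    raise RuntimeError(
        f"could not reach {target}% pairwise divergence in {max_retries} tries"
    )


def simulate_hor_array(
    cset: MonomerConsensusSet,
    n_copies: int,
    params: HORSimParams,
    rng: np.random.Generator,
    seq_id: str = "sim",
    array_name: str = "array1",
) -> tuple[str, TruthAnnotation]:
    """Tandem array of n_copies HOR copies, each an independently mutated
    copy of the m1+m2+...+mk unit, with exact truth coordinates."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    truth = TruthAnnotation()
    parts: list[str] = []
    pos = 0
    for ci in range(n_copies):
        copy_start = pos
        nsubs = 0
        # mutate monomer-wise so truth boundaries stay exact under indels
        for label, mono in cset.monomers:
            mutated, ns = _substitute(mono, params.copy_substitution_rate, rng)
            mutated = _indel(mutated, params.copy_indel_rate, rng)
            nsubs += ns
            truth.monomers.append(
                Interval(seq_id, pos, pos + len(mutated), name=label)
            )
            parts.append(mutated)
            pos += len(mutated)
        truth.copies.append(
            Interval(seq_id, copy_start, pos, name=f"{array_name}:copy{ci + 1}")
        )
        truth.substitutions_per_copy.append(nsubs)
    truth.arrays.append(Interval(seq_id, 0, pos, name=array_name))
    return "".join(parts), truth


def simulate_genome(
    params: HORSimParams, rng: np.random.Generator | None = None,
    seq_id: str = "sim_genome",
) -> tuple[NamedSequence, TruthAnnotation]:
    """Random flanks + tandem HOR arrays separated by random gaps, plus the
    consensus set used, recoverable via the returned truth.

    The monomer consensuses are drawn first from the same generator, so a
    fixed seed reproduces the genome byte-for-byte.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cset = make_monomer_consensuses(params, rng)
    return simulate_genome_with_cset(cset, params, rng, seq_id=seq_id)


def simulate_genome_with_cset(
    cset: MonomerConsensusSet,
    params: HORSimParams,
    rng: np.random.Generator,
    seq_id: str = "sim_genome",
) -> tuple[NamedSequence, TruthAnnotation]:
    parts: list[str] = [_random_seq(rng, params.flank_length, params.gc_content)]
    pos = params.flank_length
    truth = TruthAnnotation()
    for ai, n in enumerate(params.array_sizes):
        if ai > 0:
            gap = _random_seq(rng, params.inter_array_gap, params.gc_content)
            parts.append(gap)
            pos += len(gap)
        arr_seq, arr_truth = simulate_hor_array(
            cset, n, params, rng, seq_id=seq_id, array_name=f"array{ai + 1}"
        )
        arr_truth = arr_truth.shifted(pos)
        truth.monomers.extend(arr_truth.monomers)
        truth.copies.extend(arr_truth.copies)
        truth.arrays.extend(arr_truth.arrays)
        truth.substitutions_per_copy.extend(arr_truth.substitutions_per_copy)
        parts.append(arr_seq)
        pos += len(arr_seq)
    parts.append(_random_seq(rng, params.flank_length, params.gc_content))
    genome = NamedSequence(id=seq_id, seq="".join(parts))
    return genome, truth


def write_truth_json(params: HORSimParams, cset: MonomerConsensusSet,
                     truth: TruthAnnotation, path) -> None:
    """Realized parameters and divergence summary of one simulation."""
    import itertools

    divs = [
        pairwise_divergence(a, b)
        for (_, a), (_, b) in itertools.combinations(cset.monomers, 2)
    ]
    payload = {
        "params": {
            "monomer_lengths": list(params.monomer_lengths),
            "intra_divergence_target": params.intra_divergence_target,
            "copy_substitution_rate": params.copy_substitution_rate,
            "copy_indel_rate": params.copy_indel_rate,
            "array_sizes": list(params.array_sizes),
            "inter_array_gap": params.inter_array_gap,
            "flank_length": params.flank_length,
            "gc_content": params.gc_content,
            "seed": params.seed,
        },
        "realized_consensus_divergences_pct": [round(d, 3) for d in divs],
        "n_arrays": len(truth.arrays),
        "n_copies": len(truth.copies),
        "n_monomers": len(truth.monomers),
        "mean_substitutions_per_copy": (
            round(float(np.mean(truth.substitutions_per_copy)), 3)
            if truth.substitutions_per_copy else 0.0
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
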