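"""Global repeat map (GRM) core.

The GRM algorithm maps a symbolic DNA sequence into a recurrence-distance
spectrum using the complete ensemble of K-strings (all overlapping windows of
length K): for every K-string, the distances between its consecutive
occurrences are accumulated into a histogram (the GRM diagram).  Tandem
repeats of unit length L place most of their K-string recurrences at distance
L, so repeat-unit and higher-order-repeat (HOR) lengths appear as peaks.
Peaks are then converted back into sequence: the "key string" of a peak cuts
the sequence into repeat copies, copies are condensed into a consensus, and
the GRM of the consensus itself exposes internal monomer substructure.

The method is robust to substitutions and indels because only a fraction of
the K-strings in a repeat copy need to survive mutation for the unit length
to dominate the spectrum; no numerical encoding of the sequence and no
statistical model of K-string frequencies is involved.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .sequence_io import Interval, NamedSequence

__all__ = [
    "KStringIndex",
    "GRMDiagram",
    "GRMPeak",
    "RepeatCopy",
    "ConsensusRepeat",
    "build_kstring_index",
    "compute_grm_diagram",
    "detect_peaks",
    "select_key_string",
    "segment_copies",
    "build_consensus",
    "internal_structure",
    "write_grm_tsv",
    "write_peaks_tsv",
    "plot_grm",
]

DEFAULT_K = 21
DEFAULT_MAX_DISTANCE = 20_000

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_BASE_RANK = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}


@dataclass
class KStringIndex:
    """Positions of every A/C/G/T-only window of length K in one sequence."""

    K: int
    seq_id: str
    occurrences: dict[str, list[int]]
    n_windows: int
    source_length: int


@dataclass
class GRMDiagram:
    """Histogram of consecutive same-K-string recurrence distances."""

    K: int
    counts: dict[int, int]
    source_length: int
    max_distance: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        """Dense counts indexed by distance (index 0 unused)."""
        if not self.counts:
            return np.zeros(1, dtype=np.int64)
        hi = max(self.counts)
        arr = np.zeros(hi + 1, dtype=np.int64)
        for d, c in self.counts.items():
            arr[d] = c
        return arr


@dataclass
class GRMPeak:
    """A repeat-length peak of the GRM diagram.

    center is the modal recurrence distance; [lo, hi] is the contiguous
    window around the mode over which the smoothed spectrum stays above a
    fraction of its modal value; mass is the summed raw frequency inside the
    window.  key_string is filled by select_key_string.
    """

    center: int
    lo: int
    hi: int
    mass: int
    key_string: str | None = None

    @property
    def window(self) -> tuple[int, int]:
        return (self.lo, self.hi)


@dataclass
class RepeatCopy:
    """One repeat copy cut from the source sequence."""

    interval: Interval
    seq: str
    divergence_to_consensus: float | None = None

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ConsensusRepeat:
    """A repeat-unit consensus with its copies and internal substructure."""

    seq: str
    copies: list[RepeatCopy] = field(default_factory=list)
    internal_peaks: list[int] = field(default_factory=list)
    monomer_boundaries: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def monomers(self) -> list[str]:
        """Monomer sequences cut at monomer_boundaries (cyclic rotation so the
        first boundary starts the first monomer)."""
        b = self.monomer_boundaries
        if len(b) < 2:
            return [self.seq] if not b else [self.seq[b[0]:] + self.seq[: b[0]]]
        rotated = self.seq[b[0]:] + self.seq[: b[0]]
        offs = [x - b[0] for x in b] + [len(self.seq)]
        return [rotated[offs[i]: offs[i + 1]] for i in range(len(b))]


def build_kstring_index(seq: NamedSequence, K: int) -> KStringIndex:
    """Index every K-length window over {A,C,G,T}; windows containing N are
    skipped but positions still refer to the full sequence."""
    L = seq.length
    if K < 1 or K > L:
        raise ValueError(f"K={K} out of range for sequence of length {L}")
    s = seq.seq
    occ: dict[str, list[int]] = defaultdict(list)
    n_windows = 0
    last_n = -1  # most recent N at or before current scan position
    for j, ch in enumerate(s):
        if ch == "N":
            last_n = j
        if j >= K - 1:
            i = j - K + 1
            if last_n < i:
                occ[s[i : j + 1]].append(i)
                n_windows += 1
    return KStringIndex(K=K, seq_id=seq.id, occurrences=dict(occ),
                        n_windows=n_windows, source_length=L)


def compute_grm_diagram(index: KStringIndex, max_distance: int = DEFAULT_MAX_DISTANCE) -> GRMDiagram:
    """Accumulate consecutive-occurrence distances of every K-string into the
    GRM histogram, ignoring distances beyond max_distance."""
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    counts: Counter[int] = Counter()
    for positions in index.occurrences.values():
        if len(positions) < 2:
            continue
        diffs = np.diff(np.asarray(positions, dtype=np.int64))
        for d in diffs[diffs <= max_distance]:
            counts[int(d)] += 1
    return GRMDiagram(K=index.K, counts=dict(counts),
                      source_length=index.source_length, max_distance=max_distance)


def detect_peaks(
    diagram: GRMDiagram,
    min_mass: int = 10,
    smoothing_window: int = 5,
    min_separation: int = 20,
    window_frac: float = 0.10,
    index: KStringIndex | None = None,
) -> list[GRMPeak]:
    """Find repeat-length peaks of the GRM diagram.

    The spectrum is smoothed with a moving average of smoothing_window bins;
    local maxima at least min_separation apart are kept; each peak window
    expands from the mode while the smoothed spectrum stays >= window_frac of
    its modal value; peaks with raw window mass < min_mass are dropped.
    Returned sorted by descending mass.  If an index is given, each peak's
    key_string is filled in.
    """
    from scipy.signal import find_peaks

    if not diagram.counts:
        return []
    raw = diagram.as_array().astype(float)
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    smooth = np.convolve(raw, kernel, mode="same")
    # pad so a maximum at either boundary is still a local maximum
    padded = np.concatenate([[0.0], smooth, [0.0]])
    locs, _ = find_peaks(padded, distance=max(1, int(min_separation)))
    locs -= 1
    peaks: list[GRMPeak] = []
    for loc in map(int, locs):
        # refine the mode on the raw histogram near the smoothed maximum
        a = max(1, loc - w)
        b = min(len(raw) - 1, loc + w)
        center = a + int(np.argmax(raw[a : b + 1]))
        if raw[center] == 0:
            continue
        thresh = window_frac * smooth[loc]
        lo = center
        while lo > 1 and smooth[lo - 1] >= thresh:
            lo -= 1
        hi = center
        while hi < len(raw) - 1 and smooth[hi + 1] >= thresh:
            hi += 1
        mass = int(raw[lo : hi + 1].sum())
        if mass < min_mass:
            continue
        peaks.append(GRMPeak(center=center, lo=lo, hi=hi, mass=mass))
    # merge duplicates created by mode refinement of adjacent smoothed maxima
    uniq: dict[tuple[int, int, int], GRMPeak] = {}
    for p in peaks:
        uniq[(p.center, p.lo, p.hi)] = p
    out = sorted(uniq.values(), key=lambda p: (-p.mass, p.center))
    if index is not None:
        for p in out:
            try:
                p.key_string = select_key_string(index, p)
            except LookupError:
                p.key_string = None
    return out


def select_key_string(index: KStringIndex, peak: GRMPeak) -> str:
    """The K-string with the most consecutive-occurrence pairs whose spacing
    falls inside the peak window; ties broken lexicographically."""
    best: tuple[int, str] | None = None
    lo, hi = peak.lo, peak.hi
    for kstr, positions in index.occurrences.items():
        if len(positions) < 2:
            continue
        npairs = sum(1 for a, b in zip(positions, positions[1:]) if lo <= b - a <= hi)
        if npairs == 0:
            continue
        if best is None or npairs > best[0] or (npairs == best[0] and kstr < best[1]):
            best = (npairs, kstr)
    if best is None:
        raise LookupError(
            f"no K-string has consecutive occurrences spaced within [{lo}, {hi}]"
        )
    return best[1]


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def segment_copies(
    seq: NamedSequence,
    key_string: str,
    peak: GRMPeak,
    length_window: tuple[float, float] | None = None,
) -> list[RepeatCopy]:
    """Cut the sequence at every key-string occurrence and keep the fragments
    whose length is consistent with the peak.

    Fragments run from one occurrence to the next, so the partial fragments
    before the first and after the last occurrence are discarded.  By default
    fragments within [0.85, 1.15] x peak.center are kept, absorbing the
    indel-driven length spread seen among real repeat copies.
    """
    positions = _find_all(seq.seq, key_string)
    if len(positions) < 2:
        raise LookupError(
            f"key string occurs {len(positions)} time(s) in {seq.id!r}; need >= 2"
        )
    if length_window is None:
        lo_len = 0.85 * peak.center
        hi_len = 1.15 * peak.center
    else:
        lo_len, hi_len = length_window
    copies: list[RepeatCopy] = []
    for a, b in zip(positions, positions[1:]):
        if lo_len <= b - a <= hi_len:
            copies.append(
                RepeatCopy(
                    interval=Interval(seq_id=seq.id, start=a, end=b, name="copy"),
                    seq=seq.seq[a:b],
                )
            )
    if len(copies) < 2:
        raise LookupError(
            f"only {len(copies)} fragment(s) within length window "
            f"[{lo_len:.0f}, {hi_len:.0f}] in {seq.id!r}"
        )
    return copies


def _align_to_template(copy_seq: str, template: str):
    """Per-template-column symbols plus insertions for one copy.

    Returns (column symbols: list over template positions of base or '-',
    insertions: dict template position -> inserted string occurring just
    before that position; position len(template) means appended at the end).
    """
    res = edlib.align(copy_seq, template, mode="NW", task="path")
    cols = ["-"] * len(template)
    inserts: dict[int, str] = {}
    qi = ti = 0
    for m in _CIGAR_RE.finditer(res["cigar"]):
        n, op = int(m.group(1)), m.group(2)
        if op in ("=", "X", "M"):
            for _ in range(n):
                cols[ti] = copy_seq[qi]
                qi += 1
                ti += 1
        elif op == "I":  # extra bases in the copy
            inserts[ti] = inserts.get(ti, "") + copy_seq[qi : qi + n]
            qi += n
        elif op == "D":  # copy lacks these template bases
            ti += n
    return cols, inserts


def _vote(counter: Counter) -> str:
    """Majority symbol; ties by base order A<C<G<T, gap losing all ties."""
    return min(counter.items(), key=lambda kv: (-kv[1], _BASE_RANK[kv[0]]))[0]


def _consensus_round(copy_seqs: list[str], template: str) -> str:
    n = len(copy_seqs)
    T = len(template)
    col_votes = [Counter() for _ in range(T)]
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    for cs in copy_seqs:
        cols, inserts = _align_to_template(cs, template)
        for t in range(T):
            col_votes[t][cols[t]] += 1
        for pos, s in inserts.items():
            ins_votes[pos][s] += 1
    parts: list[str] = []
    for t in range(T + 1):
        if t in ins_votes and sum(ins_votes[t].values()) * 2 > n:
            # insertion supported by a majority of copies: majority string,
            # ties broken lexicographically
            parts.append(min(ins_votes[t].items(), key=lambda kv: (-kv[1], kv[0]))[0])
        if t < T:
            sym = _vote(col_votes[t])
            if sym != "-":
                parts.append(sym)
    return "".join(parts)


def _medoid(seqs: list[str]) -> int:
    """Index of the sequence minimizing summed edit distance to the others."""
    n = len(seqs)
    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d
    return int(np.argmin(dist.sum(axis=1)))


def build_consensus(copies: list[RepeatCopy], max_rounds: int = 5) -> ConsensusRepeat:
    """Iterative majority-vote consensus of repeat copies.

    The medoid copy seeds the template; every copy is globally aligned to the
    template with unit edit costs and each template column takes the majority
    symbol (gap-majority columns are deleted, insertions supported by a
    majority of copies are retained).  The vote repeats with the new
    consensus until it is unchanged or max_rounds is reached.  Each copy's
    divergence is 100 x edit distance / consensus length.
    """
    if len(copies) < 2:
        raise ValueError("need >= 2 copies to build a consensus")
    seqs = [c.seq for c in copies]
    template = seqs[_medoid(seqs)]
    for _ in range(max_rounds):
        new = _consensus_round(seqs, template)
        if new == template:
            break
        template = new
    out_copies = [
        replace(
            c,
            divergence_to_consensus=100.0
            * edlib.align(c.seq, template, mode="NW", task="distance")["editDistance"]
            / len(template),
        )
        for c in copies
    ]
    return ConsensusRepeat(seq=template, copies=out_copies)


def internal_structure(
    consensus: ConsensusRepeat,
    K: int = 13,
    min_mass: int = 5,
    smoothing_window: int = 5,
    min_separation: int = 20,
) -> ConsensusRepeat:
    """Detect sub-repeat (monomer) periodicity inside a consensus unit.

    The GRM is computed on the doubled consensus (the unit concatenated with
    itself) so periodicity that wraps across the tandem junction is visible;
    distances are capped just below the unit length to exclude the trivial
    full-length period introduced by the doubling.  The default K is shorter
    than the genome-scale default because sub-repeats inside one unit can
    diverge by ~20%, which leaves few shared 21-strings but plenty of shared
    13-strings; within a few-kb consensus a 13-string is still specific.
    If the smallest internal
    peak p divides the unit into n ~= length/p parts, the consensus is cut at
    the key string of that peak, extending cyclically with step p where the
    key string itself was not conserved in every monomer.
    """
    L = consensus.length
    doubled = NamedSequence(id="doubled", seq=consensus.seq + consensus.seq)
    if K >= L:
        raise ValueError(f"K={K} too large for consensus of length {L}")
    index = build_kstring_index(doubled, K)
    diagram = compute_grm_diagram(index, max_distance=L - 1)
    peaks = detect_peaks(
        diagram,
        min_mass=min_mass,
        smoothing_window=smoothing_window,
        min_separation=min_separation,
    )
    internal = sorted(int(p.center) for p in peaks)
    boundaries: list[int] = []
    if internal:
        p_min = internal[0]
        n = round(L / p_min)
        if n >= 2:
            peak = next(p for p in peaks if p.center == p_min)
            key = select_key_string(index, peak)
            occ = [q for q in _find_all(consensus.seq, key)]
            if occ:
                chosen = [occ[0]]
                for q in occ[1:]:
                    if all(_cyclic_gap(q, c, L) > p_min / 4 for c in chosen):
                        chosen.append(q)
                # fill missing boundaries by stepping p_min from the first cut
                j = 1
                while len(chosen) < n and j < 2 * n:
                    cand = (chosen[0] + j * p_min) % L
                    if all(_cyclic_gap(cand, c, L) > p_min / 4 for c in chosen):
                        chosen.append(cand)
                    j += 1
                boundaries = sorted(chosen)[:n]
    return ConsensusRepeat(
        seq=consensus.seq,
        copies=consensus.copies,
        internal_peaks=internal,
        monomer_boundaries=boundaries,
    )


def _cyclic_gap(a: int, b: int, L: int) -> int:
    d = abs(a - b) % L
    return min(d, L - d)


def write_grm_tsv(diagram: GRMDiagram, path) -> None:
    """Two-column TSV: distance_bp, count."""
    with open(path, "w") as fh:
        fh.write("distance_bp\tcount\n")
        for d in sorted(diagram.counts):
            fh.write(f"{d}\t{diagram.counts[d]}\n")


def write_peaks_tsv(peaks: list[GRMPeak], path) -> None:
    with open(path, "w") as fh:
        fh.write("center\tlo\thi\tmass\tkey_string\n")
        for p in peaks:
            fh.write(f"{p.center}\t{p.lo}\t{p.hi}\t{p.mass}\t{p.key_string or '.'}\n")


def plot_grm(diagram: GRMDiagram, path, title: str | None = None) -> None:
    """Distance-frequency plot with log-scaled y axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = diagram.as_array()
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.vlines(np.nonzero(arr)[0], 0, arr[arr > 0], lw=0.8)
    ax.set_yscale("symlog")
    ax.set_xlabel("recurrence distance (bp)")
    ax.set_ylabel("frequency")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
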