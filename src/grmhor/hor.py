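"""Higher-order-repeat (HOR) annotation.

Classifies monomer segments against a set of consensus monomers by global
edit (Levenshtein) distance, calls 3mer HOR copies from runs of adjacent
monomer hits, marks copies canonical when they satisfy the definitional
predicate (three monomers m1, m2, m3 in cyclic order, each diverging < 5%
from its consensus, lying in a tandem run of HOR copies), groups canonical
copies into tandem arrays, and computes the inter-copy vs intra-copy
divergence contrast that defines a genuine HOR: whole copies resemble each
other far more (~1-2%) than the monomers within one copy resemble each
other (~20%).

Divergence normalizations (fixed so reports are reproducible): monomer
classification divides the edit distance by the consensus length; pairwise
copy/monomer divergence divides by the longer of the two sequences.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import edlib

from .sequence_io import Interval

__all__ = [
    "MonomerConsensusSet",
    "MonomerHit",
    "HORCopy",
    "HORArray",
    "classify_monomer",
    "call_hor_copies",
    "mark_canonical",
    "group_arrays",
    "array_divergences",
    "pairwise_divergence",
    "write_monomer_table",
    "write_array_json",
]

DEFAULT_DIV_THRESHOLD = 5.0
DEFAULT_MAX_GAP = 100
DEFAULT_MIN_TANDEM = 3


@dataclass
class MonomerConsensusSet:
    """Ordered labelled consensus monomers (e.g. m1, m2, m3)."""

    monomers: list[tuple[str, str]]  # (label, sequence)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.monomers]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate monomer labels")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.monomers]

    def seq(self, label: str) -> str:
        for lab, s in self.monomers:
            if lab == label:
                return s
        raise KeyError(label)

    def min_length(self) -> int:
        return min(len(s) for _, s in self.monomers)


@dataclass
class MonomerHit:
    """A located monomer occurrence with its best consensus label."""

    interval: Interval
    label: str
    divergence: float
    seq: str = ""

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class HORCopy:
    """An ordered group of adjacent monomer hits forming one HOR copy.

    category: 'candidate' (complete cyclic triple under the divergence
    threshold), 'above_threshold', 'partial' (1-2 monomers), or
    'out_of_order'.  canonical is set by mark_canonical.
    """

    monomer_hits: list[MonomerHit]
    category: str = "candidate"
    canonical: bool = False

    @property
    def start(self) -> int:
        return self.monomer_hits[0].start

    @property
    def end(self) -> int:
        return self.monomer_hits[-1].end

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.monomer_hits]

    def sequence(self, source: str) -> str:
        return source[self.start : self.end]


@dataclass
class HORArray:
    """A maximal tandem run of canonical HOR copies."""

    copies: list[HORCopy]
    region_label: str = "."
    inter_copy_divergence: float | None = None
    intra_copy_divergence: float | None = None

    @property
    def start(self) -> int:
        return self.copies[0].start

    @property
    def end(self) -> int:
        return self.copies[-1].end

    @property
    def n_copies(self) -> int:
        return len(self.copies)


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def pairwise_divergence(a: str, b: str) -> float:
    """Percent edit distance normalized by the longer sequence."""
    return 100.0 * edit_distance(a, b) / max(len(a), len(b))


def classify_monomer(segment: str, cset: MonomerConsensusSet) -> tuple[str, float]:
    """Best consensus label for a segment and its percent divergence.

    Divergence is 100 x global edit distance / consensus length; ties are
    broken by consensus list order.
    """
    if not segment:
        raise ValueError("empty segment")
    if not cset.monomers:
        raise ValueError("empty consensus set")
    best: tuple[float, int, str] | None = None
    for order, (label, cseq) in enumerate(cset.monomers):
        div = 100.0 * edit_distance(segment, cseq) / len(cseq)
        if best is None or div < best[0]:
            best = (div, order, label)
    return best[2], best[0]


def _is_cyclic_triple(labels: list[str], base: list[str]) -> bool:
    """True if labels are the base labels in some cyclic rotation."""
    if len(labels) != len(base) or set(labels) != set(base):
        return False
    k = len(base)
    start = base.index(labels[0])
    return all(labels[i] == base[(start + i) % k] for i in range(k))


def call_hor_copies(
    hits: list[MonomerHit],
    max_gap: int = DEFAULT_MAX_GAP,
    div_threshold: float = DEFAULT_DIV_THRESHOLD,
    labels: list[str] | None = None,
) -> list[HORCopy]:
    """Group adjacent monomer hits into HOR copies.

    Hits are first split into runs where consecutive hits are separated by at
    most max_gap bp.  Within a run, every three consecutive hits covering the
    full label set in cyclic order are emitted as one copy ('candidate' when
    all three divergences are below div_threshold, otherwise
    'above_threshold'); leftover hits between triples become 'partial' or
    'out_of_order' copies.
    """
    if not hits:
        return []
    if labels is None:
        labels = sorted({h.label for h in hits})
    k = len(labels)
    copies: list[HORCopy] = []

    def flush(leftover: list[MonomerHit]) -> None:
        if leftover:
            cat = "partial" if len(leftover) < k else "out_of_order"
            copies.append(HORCopy(monomer_hits=list(leftover), category=cat))
            leftover.clear()

    runs: list[list[MonomerHit]] = [[hits[0]]]
    for prev, h in zip(hits, hits[1:]):
        if h.start < prev.start:
            raise ValueError("hits must be sorted by start")
        if h.start - prev.end <= max_gap:
            runs[-1].append(h)
        else:
            runs.append([h])

    for run in runs:
        leftover: list[MonomerHit] = []
        i = 0
        while i < len(run):
            window = run[i : i + k]
            if len(window) == k and _is_cyclic_triple([h.label for h in window], labels):
                flush(leftover)
                cat = (
                    "candidate"
                    if all(h.divergence < div_threshold for h in window)
                    else "above_threshold"
                )
                copies.append(HORCopy(monomer_hits=window, category=cat))
                i += k
            else:
                leftover.append(run[i])
                i += 1
        flush(leftover)
    copies.sort(key=lambda c: c.start)
    return copies


def mark_canonical(
    copies: list[HORCopy],
    min_tandem: int = DEFAULT_MIN_TANDEM,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[HORCopy]:
    """Mark candidate copies canonical when they lie in a tandem run of at
    least min_tandem candidate copies (gaps between consecutive copies at
    most max_gap bp)."""
    out = [replace(c, monomer_hits=c.monomer_hits) for c in copies]
    run: list[HORCopy] = []

    def close(run: list[HORCopy]) -> None:
        if len(run) >= min_tandem:
            for c in run:
                c.canonical = True

    prev = None
    for c in out:
        c.canonical = False
        if c.category != "candidate":
            prev = None
            close(run)
            run = []
            continue
        if prev is not None and c.start - prev.end <= max_gap:
            run.append(c)
        else:
            close(run)
            run = [c]
        prev = c
    close(run)
    return out


def group_arrays(
    copies: list[HORCopy],
    max_gap: int = DEFAULT_MAX_GAP,
    regions: list[Interval] | None = None,
    source: str | None = None,
) -> list[HORArray]:
    """Partition canonical copies into maximal tandem arrays.

    If region intervals are supplied, an array inherits the name of the
    region containing its midpoint.  If the source sequence is supplied the
    inter/intra-copy divergence statistics are computed for each array.
    """
    canon = [c for c in copies if c.canonical]
    if not canon:
        return []
    arrays: list[HORArray] = []
    cur = [canon[0]]
    for prev, c in zip(canon, canon[1:]):
        if c.start - prev.end <= max_gap:
            cur.append(c)
        else:
            arrays.append(HORArray(copies=cur))
            cur = [c]
    arrays.append(HORArray(copies=cur))
    for arr in arrays:
        if regions:
            mid = (arr.start + arr.end) // 2
            for iv in regions:
                if iv.start <= mid < iv.end:
                    arr.region_label = iv.name
                    break
        if source is not None and arr.n_copies >= 2:
            arr.inter_copy_divergence, arr.intra_copy_divergence = array_divergences(
                arr, source
            )
    return arrays


def array_divergences(array: HORArray, source: str) -> tuple[float, float]:
    """Inter-copy and intra-copy percent divergences of a tandem array.

    inter: mean over all unordered pairs of copies of the pairwise divergence
    of the full copy sequences.  intra: mean over copies of the mean pairwise
    divergence among that copy's monomer sequences.  Both normalize the edit
    distance by the longer sequence of the pair.
    """
    if array.n_copies < 2:
        raise ValueError("need >= 2 copies for divergence statistics")
    copy_seqs = [c.sequence(source) for c in array.copies]
    inter_vals = [
        pairwise_divergence(a, b) for a, b in itertools.combinations(copy_seqs, 2)
    ]
    intra_means = []
    for c in array.copies:
        mono = [source[h.start : h.end] for h in c.monomer_hits]
        if len(mono) < 2:
            continue
        vals = [pairwise_divergence(a, b) for a, b in itertools.combinations(mono, 2)]
        intra_means.append(sum(vals) / len(vals))
    inter = sum(inter_vals) / len(inter_vals)
    intra = sum(intra_means) / len(intra_means) if intra_means else float("nan")
    return inter, intra


def write_monomer_table(hits: list[MonomerHit], path) -> None:
    """Per-monomer TSV: ordinal number, length, type, divergence (2 decimals),
    1-based start position."""
    with open(path, "w") as fh:
        fh.write("Mon. No.\tL(bp)\tMon. type\tDiv. (%)\tStart\n")
        for i, h in enumerate(hits, start=1):
            fh.write(
                f"{i}\t{h.length}\t{h.label}\t{h.divergence:.2f}\t{h.start + 1}\n"
            )


def write_array_json(arrays: list[HORArray], copies: list[HORCopy], path) -> None:
    """Per-array JSON summary plus the copy census by category."""
    census = {}
    for c in copies:
        key = "canonical" if c.canonical else f"noncanonical_{c.category}"
        census[key] = census.get(key, 0) + 1
    payload = {
        "n_arrays": len(arrays),
        "total_canonical_copies": sum(a.n_copies for a in arrays),
        "copy_census": census,
        "arrays": [
            {
                "region": a.region_label,
                "start": a.start,
                "end": a.end,
                "n_copies": a.n_copies,
                "inter_copy_divergence_pct": _rnd(a.inter_copy_divergence),
                "intra_copy_divergence_pct": _rnd(a.intra_copy_divergence),
            }
            for a in arrays
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _rnd(x: float | None) -> float | None:
    return None if x is None else round(x, 4)
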