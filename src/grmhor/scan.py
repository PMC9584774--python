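"""Approximate monomer search along a genomic sequence.

Locates occurrences of consensus monomers (e.g. the ~1.6-kb NBPF monomers
m1/m2/m3) anywhere in a sequence by edit-distance alignment, without
requiring a GRM peak first.  The strategy is seed-and-extend: exact seed
words sampled from each consensus are looked up in a window index of the
genome, seed matches are clustered into candidate loci, and each locus is
verified by infix (semi-global) alignment of the consensus against the
locus, bounded at max_divergence.  Overlapping hits from different
consensuses are resolved greedily by ascending divergence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib

from .hor import MonomerConsensusSet, MonomerHit
from .sequence_io import Interval, NamedSequence, reverse_complement

__all__ = ["ScanParams", "scan_genome", "resolve_overlaps", "write_hits_bed"]


@dataclass
class ScanParams:
    """Knobs of the monomer scan.

    max_divergence: reject alignments above this percent edit distance
    (relative to the consensus length).  Large values recover old, dispersed
    monomer relics; small values keep only near-perfect copies.
    min_hit_length_fraction: minimum aligned genomic footprint relative to
    the consensus length.  seed_length/seed_stride control seed sensitivity.
    """

    max_divergence: float = 25.0
    min_hit_length_fraction: float = 0.8
    both_strands: bool = False
    seed_length: int = 12
    seed_stride: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.max_divergence < 100):
            raise ValueError("max_divergence must be in (0, 100)")
        if not (0 < self.min_hit_length_fraction <= 1):
            raise ValueError("min_hit_length_fraction must be in (0, 1]")


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            idx[w].append(i)
    return idx


def _candidate_loci(consensus: str, genome_idx: dict[str, list[int]],
                    params: ScanParams) -> list[int]:
    """Approximate start positions of consensus-like loci from seed matches.

    Each seed hit votes for a locus start (genome position minus seed offset);
    votes are clustered with a gap of half the consensus length.
    """
    k = params.seed_length
    anchors: list[int] = []
    for off in range(0, max(1, len(consensus) - k + 1), params.seed_stride):
        w = consensus[off : off + k]
        if len(w) < k or "N" in w:
            continue
        for pos in genome_idx.get(w, ()):
            anchors.append(pos - off)
    if not anchors:
        return []
    anchors.sort()
    gap = max(50, len(consensus) // 2)
    loci = [anchors[0]]
    cluster = [anchors[0]]
    for a in anchors[1:]:
        if a - cluster[-1] <= gap:
            cluster.append(a)
        else:
            loci[-1] = cluster[len(cluster) // 2]  # median anchor of the cluster
            loci.append(a)
            cluster = [a]
    loci[-1] = cluster[len(cluster) // 2]
    return loci


def _align_locus(consensus: str, label: str, seq: str, seq_id: str, locus: int,
                 params: ScanParams, strand: str, src_len: int) -> MonomerHit | None:
    """Verify one candidate locus by banded infix alignment."""
    L = len(consensus)
    max_ed = int(params.max_divergence / 100.0 * L)
    pad = max_ed + params.seed_length
    a = max(0, locus - pad)
    b = min(len(seq), locus + L + pad)
    if b - a < int(params.min_hit_length_fraction * L):
        return None
    res = edlib.align(consensus, seq[a:b], mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    start, end = a + s, a + e + 1
    if end - start < params.min_hit_length_fraction * L:
        return None
    div = 100.0 * res["editDistance"] / L
    if strand == "-":
        start, end = src_len - end, src_len - start
    return MonomerHit(
        interval=Interval(seq_id=seq_id, start=start, end=end, strand=strand,
                          name=label),
        label=label,
        divergence=div,
    )


def scan_genome(
    seq: NamedSequence,
    cset: MonomerConsensusSet,
    params: ScanParams | None = None,
) -> list[MonomerHit]:
    """Find all monomer-like loci with divergence <= max_divergence.

    Every consensus is searched independently; overlapping hits (the same
    locus matching two consensuses) are then resolved by ascending
    divergence.  Hits are returned in coordinate order.  Coordinates of
    minus-strand hits (both_strands=True) refer to the forward sequence.
    """
    if params is None:
        params = ScanParams()
    if not cset.monomers:
        raise ValueError("empty consensus set")
    if seq.length < cset.min_length() * params.min_hit_length_fraction:
        return []
    strands = [("+", seq.seq)]
    if params.both_strands:
        strands.append(("-", reverse_complement(seq.seq)))
    hits: list[MonomerHit] = []
    for strand, s in strands:
        genome_idx = _seed_index(s, params.seed_length)
        for label, consensus in cset.monomers:
            for locus in _candidate_loci(consensus, genome_idx, params):
                hit = _align_locus(consensus, label, s, seq.id, locus, params,
                                   strand, seq.length)
                if hit is not None:
                    hits.append(hit)
    hits = resolve_overlaps(
        sorted(hits, key=lambda h: (h.start, h.end, h.label))
    )
    for h in hits:
        h.seq = seq.seq[h.start : h.end]
        if h.interval.strand == "-":
            h.seq = reverse_complement(h.seq)
    return hits


def resolve_overlaps(hits: list[MonomerHit], max_overlap_fraction: float = 0.10
                     ) -> list[MonomerHit]:
    """Greedy non-redundant hit selection.

    Hits are taken in order of ascending divergence (ties: leftmost start,
    then label order); a hit is kept only if it overlaps every already-kept
    hit by at most max_overlap_fraction of its own length.  Output is sorted
    by coordinate.
    """
    ranked = sorted(hits, key=lambda h: (h.divergence, h.start, h.label))
    kept: list[MonomerHit] = []
    for h in ranked:
        budget = max_overlap_fraction * h.length
        ok = True
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > budget:
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def write_hits_bed(hits: list[MonomerHit], path) -> None:
    """BED6+1: chrom, start, end, label, score 0, strand, divergence pct."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.interval.seq_id}\t{h.start}\t{h.end}\t{h.label}\t0\t"
                f"{h.interval.strand}\t{h.divergence:.2f}\n"
            )


def plot_monomer_track(hits: list[MonomerHit], path, seq_length: int | None = None,
                       title: str | None = None) -> None:
    """Monomer-distribution track: one colored tick per hit (m1 green,
    m2 red, m3 blue, others grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"m1": "tab:green", "m2": "tab:red", "m3": "tab:blue"}
    fig, ax = plt.subplots(figsize=(10, 1.8))
    for h in hits:
        ax.vlines(h.start, 0, 1, color=colors.get(h.label, "0.5"), lw=1.2)
    if seq_length:
        ax.set_xlim(0, seq_length)
    ax.set_yticks([])
    ax.set_xlabel("position (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
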