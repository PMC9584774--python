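"""Independent reference implementations used only to check the package.

These are deliberately written from the definitions (full dynamic
programming, direct enumeration) and share no code with the implementation
under test.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict

import numpy as np


def levenshtein_oracle(a: str, b: str) -> int:
    """Full-matrix unit-cost edit distance.

    Row recurrence vectorized exactly: the horizontal (insertion) chain
    min_{k<=j} E[k] + (j - k) is a prefix minimum of E[k] - k.
    """
    n = len(b)
    if n == 0:
        return len(a)
    prev = np.arange(n + 1, dtype=np.int64)
    bb = np.frombuffer(b.encode(), dtype="S1")
    idx = np.arange(n + 1, dtype=np.int64)
    for i in range(1, len(a) + 1):
        cost = (bb != a[i - 1].encode()).astype(np.int64)
        e = np.empty(n + 1, dtype=np.int64)
        e[0] = i
        e[1:] = np.minimum(prev[:-1] + cost, prev[1:] + 1)
        prev = np.minimum.accumulate(e - idx) + idx
    return int(prev[n])


def grm_census_oracle(seq: str, K: int, max_distance: int) -> dict[int, int]:
    """Brute-force consecutive same-K-string pair census.

    Enumerates every window directly, skips windows containing N, and counts
    each consecutive-occurrence distance at most max_distance.
    """
    occ: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - K + 1):
        w = seq[i : i + K]
        if "N" not in w:
            occ[w].append(i)
    counts: Counter[int] = Counter()
    for positions in occ.values():
        for a, b in zip(positions, positions[1:]):
            if b - a <= max_distance:
                counts[b - a] += 1
    return dict(counts)


def greedy_overlap_reference(hits, max_overlap_fraction: float = 0.10):
    """Direct restatement of the overlap-resolution rule for small inputs."""
    order = sorted(hits, key=lambda h: (h.divergence, h.start, h.label))
    kept = []
    for h in order:
        if all(
            min(h.end, k.end) - max(h.start, k.start) <= max_overlap_fraction * (h.end - h.start)
            for k in kept
        ):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end))


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def mutate_substitutions(rng: random.Random, seq: str, n: int) -> str:
    """Exactly n substitutions at n distinct positions."""
    positions = rng.sample(range(len(seq)), n)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)
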