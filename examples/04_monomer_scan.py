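"""Locate dispersed monomer copies by edit-distance scan.

Plants two mutated copies of a consensus monomer (5% and 15% divergence) far
apart in random sequence and recovers both with their divergences, showing
how the max_divergence knob separates recent from ancient copies.
"""

import random

from grmhor import MonomerConsensusSet, NamedSequence, ScanParams, scan_genome

rng = random.Random(12)
dna = lambda n: "".join(rng.choice("ACGT") for _ in range(n))


def mutate(seq, n):
    out = list(seq)
    for p in rng.sample(range(len(seq)), n):
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


m1 = dna(400)
cset = MonomerConsensusSet(monomers=[("m1", m1)])
genome = NamedSequence(
    id="toy",
    seq=dna(3000) + mutate(m1, 20) + dna(3000) + mutate(m1, 60) + dna(3000),
)

for cutoff in (10.0, 25.0):
    hits = scan_genome(genome, cset, ScanParams(max_divergence=cutoff))
    located = [f"{h.start}-{h.end} ({h.divergence:.1f}%)" for h in hits]
    print(f"max_divergence {cutoff:>4}%: {len(hits)} hit(s): {', '.join(located)}")
print("-> the 5%-divergent copy is found at both cutoffs; the 15%-divergent")
print("   relic only appears once the divergence interval is widened.")
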