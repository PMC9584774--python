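"""Full HOR annotation at the default NBPF-like regime.

Simulates the default genome (four arrays of 19/13/11/7 HOR copies built
from ~1.6-kb monomers at ~18% mutual divergence, 0.8% per-copy
substitutions), scans it with the consensus monomers, calls HOR copies,
marks canonical ones and groups tandem arrays, then prints the census and
the divergence contrast that defines a higher-order repeat.
"""

import numpy as np

from grmhor import (
    HORSimParams,
    ScanParams,
    call_hor_copies,
    group_arrays,
    make_monomer_consensuses,
    mark_canonical,
    scan_genome,
)
from grmhor.synthetic import simulate_genome_with_cset

params = HORSimParams(seed=1)
rng = np.random.default_rng(params.seed)
cset = make_monomer_consensuses(params, rng)
genome, truth = simulate_genome_with_cset(cset, params, rng)
print(f"simulated genome: {genome.length} bp, {len(truth.copies)} planted copies")

hits = scan_genome(genome, cset, ScanParams())
print(f"monomer hits: {len(hits)} (planted monomers: {len(truth.monomers)})")

copies = mark_canonical(call_hor_copies(hits, labels=cset.labels))
arrays = group_arrays(copies, source=genome.seq)
print(f"tandem arrays: {len(arrays)}; canonical copies per array: "
      f"{[a.n_copies for a in arrays]}")
for a in arrays:
    print(f"  array {a.start}-{a.end}: {a.n_copies} copies, "
          f"inter-copy divergence {a.inter_copy_divergence:.2f}%, "
          f"intra-copy divergence {a.intra_copy_divergence:.2f}%")
print("-> whole HOR copies are ~10x more alike (~1.6%) than the monomers")
print("   inside each copy (~19%): the signature of a higher-order repeat.")
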