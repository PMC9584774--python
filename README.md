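# grmhor

Detection and annotation of **higher-order repeats (HORs)** in DNA sequences
with the **global repeat map (GRM)** algorithm, plus edit-distance monomer
scanning and canonical 3mer HOR calling for NBPF-like tandem arrays.

## The problem

Tandemly repeated DNA is often organized on two levels: a *primary* repeat
unit (monomer) and a *secondary* higher-order unit composed of several
divergent monomers. In a genuine HOR, whole HOR copies are far more similar
to each other (~1–2% divergence) than the monomers within one copy are to
each other (~20%) — the classic pattern of centromeric α-satellite HORs, and
of the ~4.77-kb 3mer HOR inside human NBPF genes, whose three ~1.6-kb
monomers (m1, m2, m3; consensus lengths 1,623 / 1,593 / 1,554 bp) correspond
to Olduvai protein domains. This package is for researchers who need to
find such structure without prior knowledge of the repeat, and to annotate
known monomers along genomic sequence.

## The method

**GRM spectrum.** For a sequence *S* and K-string length *K*, index every
window of length *K* (the complete K-string ensemble). For each K-string
with occurrence positions p₁ < p₂ < … < pₘ, accumulate the consecutive
recurrence distances pᵢ₊₁ − pᵢ into a histogram *G(d)*. A tandem repeat of
unit length *L* concentrates recurrences at *d = L*, so repeat-unit and HOR
lengths appear as peaks of *G* — robust to substitutions and indels, with no
statistical tuning of individual K-strings.

**From peak to sequence.** The *key string* of a peak (the K-string with the
most in-window recurrences) cuts *S* into repeat copies; an iterative
medoid-seeded majority vote over globally aligned copies yields the
consensus unit; the GRM of the doubled consensus exposes internal monomer
periodicity and boundaries.

**Annotation.** Monomer hits are found by seed-and-extend semi-global
alignment against consensus monomers, labelled by the argmin of
`100 · edit_distance(segment, consensus) / |consensus|`. A **canonical 3mer
HOR copy** is three adjacent monomers covering (m1, m2, m3) in cyclic order,
each diverging < 5% from its consensus, lying in a tandem run of ≥ 3 copies.
Canonical copies are grouped into tandem arrays with inter-copy and
intra-copy divergence statistics.

## Worked example

`python examples/03_annotate_hor_arrays.py` simulates the default regime —
four tandem arrays of 19/13/11/7 HOR copies built from ~1.6-kb monomers at
~18% mutual divergence, 0.8% substitutions per copy — and annotates it:

```
simulated genome: 273491 bp, 50 planted copies
monomer hits: 150 (planted monomers: 150)
tandem arrays: 4; canonical copies per array: [19, 13, 11, 7]
  array 10000-100627: 19 copies, inter-copy divergence 1.64%, intra-copy divergence 18.96%
  ...
```

All 150 monomers are recovered and labelled, the 50 planted copies are all
called canonical in four arrays, and the divergence contrast (~1.6% between
copies vs ~19% between the monomers inside a copy) is the order-of-magnitude
signature separating a true HOR from a plain tandem repeat.

The other examples show the discovery path: `01_grm_spectrum.py` (spectrum
and peaks), `02_consensus_and_monomers.py` (peak → copies → consensus →
internal 3mer structure), `04_monomer_scan.py` (divergence-threshold scan).

A thin CLI wraps the same functions:

```bash
grmhor simulate --seed 1 --out sim/
grmhor grm sim/genome.fasta --out out/            # spectrum + peaks TSV
grmhor annotate sim/genome.fasta sim/consensus_monomers.fasta --out out/
```

## Scope

Desk-scale analysis and simulation. The tool applies unchanged to real
assemblies (a whole chromosome FASTA is just a larger input), but no
download machinery is included and no claims are packaged about specific
accessions.
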