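# Methods

## The GRM recurrence spectrum

The global repeat map of a sequence is the histogram of distances between
*consecutive* occurrences of identical K-strings, taken over the complete
ensemble of A/C/G/T-only windows (windows containing N are skipped; positions
are kept in assembly coordinates so reported intervals remain valid).
Counting only consecutive pairs — rather than all pairs — makes a perfect
tandem of unit length *L* produce a spectrum supported exactly on {*L*}
(each phase K-string recurs only at distance *L*) and keeps totals bounded;
counting all pairs would smear mass onto every multiple of *L*. The total
count is conserved: it equals a brute-force census of consecutive
same-K-string pairs under the same distance cap, which the test suite checks
against an independent enumeration.

"Frequency domain" here means this distance-frequency histogram; no Fourier
transform is involved.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| K (genome scale) | 21 | bp | long enough that chance recurrence within the 20-kb cap is negligible on chromosome-scale input (4²¹ ≈ 4·10¹²); short enough that ~1.6% copy divergence leaves ~70% of windows intact, so unit-length peaks dominate |
| K (internal structure) | 13 | bp | monomers within one HOR unit diverge ~20%, leaving few shared 21-strings but ~8% of 13-strings shared; within a few-kb consensus a 13-string is still effectively unique |
| max_distance | 20,000 | bp | covers HOR units of a few kb with margin, excludes inter-array distances, bounds memory |
| smoothing window | 5 | bp | absorbs the ±few-bp indel jitter of real copy lengths before local-maximum detection |
| peak window fraction | 0.10 | — | a peak's window expands from the mode while the smoothed spectrum stays ≥ 10% of the modal value |
| min_mass | 10 | pairs | discards isolated coincidences; exposed because appropriate mass scales with input length |

Peak detection smooths the dense spectrum with a moving average, finds local
maxima (scipy), refines each mode on the raw histogram, expands the window,
and ranks peaks by raw window mass. Sensitivity of peak recovery across
K ∈ {15, 21, 31} on the simulated regime is part of the test suite's planted
recovery checks (K = 21 default; shorter/longer K shift mass but not the
modal distance).

## Segmentation and consensus

The **key string** of a peak is the K-string with the most consecutive
recurrences inside the peak window (ties broken lexicographically for
determinism). Cutting at its occurrences yields repeat copies; fragments
outside [0.85, 1.15] × peak center are discarded — this absorbs the ±3–5%
monomer length spread seen in real NBPF copies while rejecting doubled
fragments where a copy's seed was mutated. Terminal partial fragments are
discarded by construction.

**Consensus.** The medoid copy (minimum summed edit distance) seeds the
template, avoiding order dependence. Each copy is globally aligned to the
template with unit edit costs (edlib); per template column the majority
symbol wins, gap-majority columns are deleted, and insertions present in a
strict majority of copies are retained (majority inserted string, ties
lexicographic). Base ties break in fixed order A < C < G < T, with gaps
losing ties, so the consensus is deterministic. The vote iterates until the
consensus is a fixed point (≤ 5 rounds; in practice 1–2). Copy divergence is
100 × edit distance / consensus length.

**Internal structure.** The GRM of the doubled consensus (unit concatenated
with itself) exposes periodicity that wraps across the tandem junction;
distances are capped at unit length − 1 to drop the trivial full-length
period the doubling introduces. If the smallest internal peak *p* divides
the unit into *n* ≈ length/*p* parts, the consensus is cut at occurrences of
that peak's key string, extended cyclically in steps of *p* where the key
string was not conserved in every monomer. Boundaries are therefore exact
where the key string survives and approximate (± the monomer length spread)
where it does not; monomer phase is arbitrary (a rotation of the true
monomers), which is immaterial downstream because annotation uses whatever
consensus set it is given.

## Monomer classification and HOR calling

Classification divergence is **100 × global edit distance / consensus
length**; pairwise copy/monomer divergence normalizes by the **longer**
sequence of the pair. Both choices are frozen so tabulated outputs are
reproducible; divergences print with 2 decimals and dot separator.
Classification returns the argmin over the consensus set, ties broken by
list order.

HOR copies are called inside runs of adjacent hits (gap ≤ 100 bp; true NBPF
monomers abut, the slack absorbs alignment jitter): every three consecutive
hits covering all labels in a consistent cyclic order — arrays may start at
any of m1/m2/m3 — form a copy, a *candidate* when all three divergences are
below the 5% threshold, otherwise *above_threshold*. Leftover hits become
*partial* (< 3 monomers) or *out_of_order* copies, so every hit is accounted
for. Candidates are **canonical** only inside a tandem run of ≥ `min_tandem`
candidate copies. `min_tandem` defaults to 3 ("in tandem with two or more
others") but is exposed because the field's definition is ambiguous for
doublets; setting it to 2 admits two-copy arrays. Raising the divergence
threshold can only add candidates, never remove them (verified as a
property test).

Array statistics: inter-copy divergence is the mean pairwise divergence of
full copy sequences over all unordered pairs; intra-copy divergence is the
mean over copies of the mean pairwise divergence among that copy's monomers.
Whether the original analyses computed inter-copy divergence on whole copies
or on position-matched monomers is not documented; whole copies are used
here as the more direct reading of "divergence between HOR copies".

## Monomer scan

Seed-and-extend: 12-bp seed words sampled every 4 bp from each consensus are
looked up in a window index of the genome; seed votes (genome position minus
consensus offset) are clustered into candidate loci; each locus is verified
by infix (semi-global) alignment bounded at `max_divergence` (default 25% —
wide enough to pick up old dispersed monomer relics, narrow enough to
exclude random matches, and explicitly a tunable "divergence interval").
At 25% divergence a 12-bp seed survives with probability ~0.03 per position,
so a ~1.6-kb monomer still yields several anchors in expectation; hits
shorter than 80% of the consensus are rejected. Overlapping hits (one locus
matching several consensuses) are resolved greedily by ascending divergence,
allowing ≤ 10% residual overlap. Minus-strand scanning is off by default and
reports forward-strand coordinates when enabled.

The contract is the result set (all loci within the divergence bound), not
the search strategy; the acceptance tests compare the scan's divergences to
unrestricted semi-global alignment of the consensus against the whole
sequence.

## Synthetic generator

The generator emulates the NBPF 3mer regime: three monomer consensuses of
1,623/1,593/1,554 bp derived from one random ancestor at ~18% mutual
divergence; HOR copies mutated from the m1+m2+m3 unit at 0.8% substitutions
and 0.05% single-base indels per copy (hence ~1.6% expected copy-pair
divergence); four arrays of 19/13/11/7 copies separated by 5-kb random gaps
inside 10-kb flanks at GC 0.41 (a typical gene-region composition).

Divergence targeting is mutate-and-measure: the per-branch substitution rate
is tuned until measured pairwise divergences fall within ±2 points of the
target (mean within ±0.5), because the measurement — not the nominal rate —
is what downstream modules see. Length differences are realized by *nested*
deletion sets from the ancestor (the shortest monomer's deletions contain
the middle one's), so the indel component of each pairwise divergence is the
pair's length difference; independent deletions would spread the three
pairwise divergences several points apart and make the band unreachable.
Copies are mutated monomer-wise so truth boundaries remain exact under
indels. All randomness flows through one seeded `numpy` generator; a fixed
seed reproduces the genome byte for byte.

What the generator does *not* model: phylogenetically structured copy
evolution (duplication trees, gene conversion), transposon insertions,
assembly gaps, and soft-masking. Passing the planted-recovery tests
therefore shows the pipeline is correct and calibrated under the stated
divergence regime, not that it is robust to every artifact of real
assemblies — on real data the same thresholds apply but hit counts depend on
assembly completeness.

Note that the measured intra-copy divergence of simulated arrays runs
~1.3 points above the 18% consensus target, because per-copy substitutions
add to the monomer-to-monomer differences; this is inherent to the model,
not a calibration error.

## Problem sizes

The default simulated regime is a ~273-kb genome (50 HOR copies of ~4.77
kb). The full pipeline (spectrum, scan, annotation, consensus) runs in a few
seconds at this size; spectra of whole chromosomes are linear in length and
bounded in memory by the distance cap. Divergence-estimator checks use 20
seeds × 10-copy arrays; classification checks use 100 random pairs up to
2 kb against a full dynamic-programming oracle.

## Degenerate inputs and tie-breaks

Empty spectra yield empty peak lists (not errors); segmentation and
consensus require ≥ 2 usable fragments/copies and raise informative errors
otherwise; N-containing windows are skipped everywhere; all tie-breaks
(majority vote, key-string selection, overlap resolution, classification)
are fixed and documented above so identical inputs give identical outputs.
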