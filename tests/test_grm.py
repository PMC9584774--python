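import random

import numpy as np
import pytest

from grmhor import (
    ConsensusRepeat,
    NamedSequence,
    build_consensus,
    build_kstring_index,
    compute_grm_diagram,
    detect_peaks,
    internal_structure,
    make_monomer_consensuses,
    segment_copies,
    select_key_string,
)
from grmhor.grm import GRMPeak
from grmhor.hor import pairwise_divergence
from grmhor.synthetic import HORSimParams

from oracle import grm_census_oracle, mutate_substitutions, random_dna


class TestKStringIndex:
    def test_homopolymer(self):
        idx = build_kstring_index(NamedSequence(id="s", seq="AAAA"), 2)
        assert idx.occurrences == {"AA": [0, 1, 2]}
        assert idx.n_windows == 3

    def test_windows_overlapping_n_skipped(self):
        idx = build_kstring_index(NamedSequence(id="s", seq="ACGNT"), 2)
        assert idx.occurrences == {"AC": [0], "CG": [1]}
        assert idx.n_windows == 2

    def test_matches_brute_force_on_random_sequence(self):
        rng = random.Random(11)
        seq = random_dna(rng, 1000, alphabet="ACGTN")
        idx = build_kstring_index(NamedSequence(id="s", seq=seq), 8)
        expected = {}
        for i in range(len(seq) - 7):
            w = seq[i : i + 8]
            if "N" not in w:
                expected.setdefault(w, []).append(i)
        assert idx.occurrences == expected
        assert idx.n_windows == sum(len(v) for v in expected.values())

    def test_occurrence_counts_sum_to_n_windows(self):
        rng = random.Random(5)
        seq = random_dna(rng, 500)
        idx = build_kstring_index(NamedSequence(id="s", seq=seq), 5)
        assert sum(len(v) for v in idx.occurrences.values()) == idx.n_windows

    @pytest.mark.parametrize("k", [0, -1, 10])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            build_kstring_index(NamedSequence(id="s", seq="ACGTACGT"), k)


class TestGRMDiagram:
    def test_exact_tandem_law(self):
        # 10 copies of a 5-bp unit: 9 consecutive pairs for the in-phase
        # K-string plus 8 for each of the other 4 phases
        s = NamedSequence(id="t", seq="ACGTT" * 10)
        d = compute_grm_diagram(build_kstring_index(s, 5))
        assert d.counts == {5: 41}
        assert d.counts == grm_census_oracle(s.seq, 5, d.max_distance)

    def test_all_unique_kstrings_gives_empty_diagram(self):
        s = NamedSequence(id="u", seq="ACGTTGCAAT")
        d = compute_grm_diagram(build_kstring_index(s, 9))
        assert d.counts == {}

    @pytest.mark.parametrize("K", [5, 8, 12, 21])
    def test_pair_census_conservation(self, K):
        rng = random.Random(100 + K)
        seq = random_dna(rng, 6000)
        d = compute_grm_diagram(build_kstring_index(NamedSequence(id="s", seq=seq), K),
                                max_distance=2000)
        assert d.counts == grm_census_oracle(seq, K, 2000)
        assert d.total == sum(grm_census_oracle(seq, K, 2000).values())

    def test_shift_invariance_under_nonrepetitive_flank(self):
        # recurrences are position differences, so a 100-bp flank that shares
        # no K-string with the rest must not change any count
        rng = random.Random(42)
        unit = random_dna(rng, 60)
        core = unit * 8
        flank = random_dna(rng, 100)
        d0 = compute_grm_diagram(
            build_kstring_index(NamedSequence(id="a", seq=core), 21))
        d1 = compute_grm_diagram(
            build_kstring_index(NamedSequence(id="b", seq=flank + core), 21))
        for dist, cnt in d0.counts.items():
            assert d1.counts.get(dist, 0) >= cnt
        assert d1.counts == grm_census_oracle(flank + core, 21, d1.max_distance)

    def test_max_distance_cap(self):
        s = NamedSequence(id="t", seq="ACGTT" * 10)
        d = compute_grm_diagram(build_kstring_index(s, 5), max_distance=4)
        assert d.counts == {}


class TestDetectPeaks:
    def test_single_bin_peak(self):
        s = NamedSequence(id="t", seq="ACGTT" * 10)
        idx = build_kstring_index(s, 5)
        peaks = detect_peaks(compute_grm_diagram(idx), min_mass=10, index=idx)
        assert len(peaks) == 1
        assert peaks[0].center == 5
        assert peaks[0].mass == 41
        assert peaks[0].key_string == "ACGTT"

    def test_empty_diagram_gives_empty_list(self):
        s = NamedSequence(id="u", seq="ACGTTGCAAT")
        d = compute_grm_diagram(build_kstring_index(s, 9))
        assert detect_peaks(d) == []

    def test_two_tandems_give_two_peaks(self):
        rng = random.Random(9)
        u1, u2 = random_dna(rng, 40), random_dna(rng, 90)
        seq = u1 * 12 + random_dna(rng, 300) + u2 * 12
        idx = build_kstring_index(NamedSequence(id="s", seq=seq), 15)
        peaks = detect_peaks(compute_grm_diagram(idx), min_mass=10, index=idx)
        centers = sorted(p.center for p in peaks)
        assert centers == [40, 90]

    @pytest.mark.parametrize("K", [15, 21, 31])
    def test_peak_recovery_is_stable_across_k(self, small_sim, K):
        # the modal recurrence distance is the unit length regardless of K,
        # as long as enough K-strings survive the copy-to-copy divergence
        cset, genome, truth = small_sim
        unit = sum(len(s) for _, s in cset.monomers)
        idx = build_kstring_index(genome, K)
        peaks = detect_peaks(compute_grm_diagram(idx, max_distance=3000), min_mass=10)
        assert peaks
        assert abs(peaks[0].center - unit) <= 5

    def test_planted_hor_peak_window_contains_unit_length(self, small_sim):
        cset, genome, truth = small_sim
        idx = build_kstring_index(genome, 21)
        peaks = detect_peaks(compute_grm_diagram(idx, max_distance=5000), min_mass=10)
        starts = {}
        for iv in truth.copies:
            starts.setdefault(iv.name.split(":")[0], []).append(iv.start)
        unit = float(np.median(np.concatenate(
            [np.diff(v) for v in starts.values() if len(v) > 1])))
        top = peaks[0]
        assert top.lo <= unit <= top.hi
        assert top.mass > 0


class TestKeyStringAndSegmentation:
    def test_tandem_key_string(self):
        s = NamedSequence(id="t", seq="ACGTT" * 10)
        idx = build_kstring_index(s, 5)
        peaks = detect_peaks(compute_grm_diagram(idx), min_mass=10)
        assert select_key_string(idx, peaks[0]) == "ACGTT"

    def test_tie_broken_lexicographically(self):
        # A and C alternate: both have 24 consecutive pairs at distance 2
        s = NamedSequence(id="t", seq="AC" * 25)
        idx = build_kstring_index(s, 1)
        peak = GRMPeak(center=2, lo=2, hi=2, mass=48)
        assert select_key_string(idx, peak) == "A"

    def test_no_qualifying_kstring(self):
        idx = build_kstring_index(NamedSequence(id="s", seq="ACGTTGCAAT"), 9)
        with pytest.raises(LookupError):
            select_key_string(idx, GRMPeak(center=5, lo=5, hi=5, mass=1))

    def test_exact_tandem_segmentation(self):
        rng = random.Random(21)
        unit = random_dna(rng, 100)
        s = NamedSequence(id="t", seq=unit * 5)
        peak = GRMPeak(center=100, lo=95, hi=105, mass=1)
        copies = segment_copies(s, unit[:20], peak)
        assert len(copies) == 4  # terminal partial fragments discarded
        assert all(c.seq == unit for c in copies)
        assert [c.interval.start for c in copies] == [0, 100, 200, 300]

    def test_key_string_absent(self):
        s = NamedSequence(id="t", seq="ACGT" * 30)
        with pytest.raises(LookupError):
            segment_copies(s, "GGGGGGG", GRMPeak(center=4, lo=4, hi=4, mass=1))

    def test_out_of_window_fragments_dropped(self):
        rng = random.Random(22)
        unit = random_dna(rng, 100)
        # one double-length fragment (missing key-string seed in the middle)
        s = NamedSequence(id="t", seq=unit * 3 + unit[25:] + unit * 2)
        copies = segment_copies(s, unit[:20], GRMPeak(center=100, lo=95, hi=105, mass=1))
        assert all(85 <= c.length <= 115 for c in copies)


class TestConsensus:
    def _copies(self, seqs):
        from grmhor import Interval, RepeatCopy

        out, pos = [], 0
        for s in seqs:
            out.append(RepeatCopy(interval=Interval("s", pos, pos + len(s)), seq=s))
            pos += len(s)
        return out

    def test_identical_copies(self):
        rng = random.Random(31)
        u = random_dna(rng, 200)
        cons = build_consensus(self._copies([u] * 5))
        assert cons.seq == u
        assert all(c.divergence_to_consensus == 0.0 for c in cons.copies)

    def test_majority_vote_corrects_isolated_errors(self):
        # 10 copies, each with 1% substitutions at distinct positions: no
        # column has a mutated majority, so the vote recovers the original
        rng = random.Random(32)
        u = random_dna(rng, 400)
        positions = rng.sample(range(400), 40)
        copies = []
        for i in range(10):
            mut = list(u)
            for p in positions[i * 4 : (i + 1) * 4]:
                mut[p] = rng.choice([c for c in "ACGT" if c != mut[p]])
            copies.append("".join(mut))
        cons = build_consensus(self._copies(copies))
        assert cons.seq == u

    def test_simulated_copies_recover_unit_length_and_divergence(self, default_sim):
        params, cset, genome, truth = default_sim
        unit_len = sum(len(s) for _, s in cset.monomers)
        copy_seqs = [genome.seq[iv.start : iv.end] for iv in truth.copies[:12]]
        cons = build_consensus(self._copies(copy_seqs))
        assert abs(cons.length - unit_len) <= 5
        mean_div = np.mean([c.divergence_to_consensus for c in cons.copies])
        # per-copy divergence to consensus ~ substitution rate + indel rate
        expected = 100 * (params.copy_substitution_rate + params.copy_indel_rate)
        assert abs(mean_div - expected) < 0.3

    def test_requires_two_copies(self):
        with pytest.raises(ValueError):
            build_consensus(self._copies(["ACGT"]))

    def test_idempotence(self):
        rng = random.Random(33)
        u = random_dna(rng, 150)
        cons = build_consensus(self._copies([u, u, u]))
        again = build_consensus(self._copies([cons.seq] * 3))
        assert again.seq == cons.seq


class TestInternalStructure:
    def test_exact_threefold_tandem(self):
        rng = random.Random(41)
        u = random_dna(rng, 200)
        cons = internal_structure(ConsensusRepeat(seq=u * 3), K=15, min_mass=5)
        assert 200 in cons.internal_peaks
        assert len(cons.monomer_boundaries) == 3
        assert sorted(len(m) for m in cons.monomers()) == [200, 200, 200]

    def test_no_internal_homology(self):
        rng = random.Random(42)
        cons = internal_structure(ConsensusRepeat(seq=random_dna(rng, 600)), K=15)
        assert cons.internal_peaks == []
        assert cons.monomer_boundaries == []

    def test_divergent_monomer_triple(self):
        # three ~1590-bp homologs at ~18% divergence: internal peaks near
        # 1.6 kb and 3.2 kb, three monomer segments
        params = HORSimParams(monomer_lengths=(1590, 1590, 1590), seed=5)
        cset = make_monomer_consensuses(params, np.random.default_rng(5))
        unit = "".join(s for _, s in cset.monomers)
        cons = internal_structure(ConsensusRepeat(seq=unit), K=21, min_mass=5)
        assert any(1400 <= p <= 1800 for p in cons.internal_peaks)
        assert len(cons.monomer_boundaries) == 3
        for m in cons.monomers():
            assert 0.8 * 1590 <= len(m) <= 1.2 * 1590
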