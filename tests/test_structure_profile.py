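import math

import numpy as np
import pytest

from acceptorkit.structure_profile import (EnergyModel, delta_pu,
                                           enumerate_structures,
                                           group_pu_profile,
                                           partition_function,
                                           pu_profile_region, pu_substring)
from conftest import make_region


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestPartitionFunction:
    def test_no_allowed_pair_gives_unit_z(self):
        res = partition_function("AAAA")
        assert res.Z == pytest.approx(1.0)
        assert np.allclose(res.unpaired_probabilities(), 1.0)

    def test_single_pair_closed_form(self):
        model = EnergyModel()
        res = partition_function("GAAAC", model)
        w = math.exp(3.0 / model.kT)
        assert res.Z == pytest.approx(1.0 + w, rel=1e-12)
        assert res.p[0, 4] == pytest.approx(w / (1.0 + w), rel=1e-12)

    def test_min_hairpin_blocks_short_loops(self):
        # ACGU: the only complementary pairs span < 3 unpaired bases
        res = partition_function("ACGU")
        assert res.Z == pytest.approx(1.0)

    def test_matches_enumeration_on_gggaaaaccc(self):
        Z, p = enumerate_structures("GGGAAAACCC")
        res = partition_function("GGGAAAACCC")
        assert abs(res.Z - Z) / Z < 1e-9
        assert np.abs(res.p - p).max() < 1e-9

    def test_oracle_equivalence_on_50_random_sequences(self, rng):
        """DP inside-outside equals exhaustive enumeration to 1e-9."""
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(8, 19)))
            Z, p = enumerate_structures(seq)
            res = partition_function(seq)
            assert abs(res.Z - Z) / Z < 1e-9, seq
            assert np.abs(res.p - p).max() < 1e-9, seq

    def test_pu_sum_rule(self, rng):
        for _ in range(20):
            seq = random_rna(rng, int(rng.integers(10, 80)))
            res = partition_function(seq)
            total = res.unpaired_probabilities() + res.p.sum(axis=1)
            assert np.abs(total - 1.0).max() < 1e-9

    def test_weaker_energies_reduce_expected_pairing(self, rng):
        """Adding +delta to every pair energy lowers the Boltzmann-mean
        number of pairs (d<m>/d delta = -Var(m)/kT <= 0), so the mean PU
        across positions never decreases.  Note the per-position PU is NOT
        monotone: weakening all pairs suppresses many-pair structures
        fastest, which can concentrate probability onto a single pair."""
        base = EnergyModel()
        weaker = base.shifted(+0.7)
        for _ in range(20):
            seq = random_rna(rng, int(rng.integers(15, 50)))
            p0 = partition_function(seq, base).p
            p1 = partition_function(seq, weaker).p
            assert p1.sum() <= p0.sum() + 1e-9

    def test_n_never_pairs(self):
        res = partition_function("GNAAAC")
        assert res.p[1].sum() == 0.0
        assert res.unpaired_probabilities()[1] == pytest.approx(1.0)

    def test_rescaling_handles_stable_long_sequences(self):
        res = partition_function("GC" * 120)
        pu = res.unpaired_probabilities()
        assert np.isfinite(res.log_Z)
        assert np.abs(pu + res.p.sum(axis=1) - 1.0).max() < 1e-9

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            partition_function("ACGX")


class TestEnumerationOracle:
    def test_refuses_long_sequences(self):
        with pytest.raises(ValueError):
            enumerate_structures("A" * 23)

    def test_empty_only_structure(self):
        Z, p = enumerate_structures("ACGU")
        assert Z == pytest.approx(1.0)
        assert p.sum() == 0.0


class TestPUProfiles:
    def test_all_a_region_fully_unpaired(self):
        region = make_region("A" * 20, "A" * 5)
        pu = pu_profile_region(region, flank=0)
        assert all(v == pytest.approx(1.0) for v in pu.values())

    def test_planted_hairpin_lowers_stem_pu(self):
        stem5, loop, stem3 = "GGGGGG", "AAAA", "CCCCCC"
        up = "U" * 4 + stem5 + loop + stem3 + "UUUUCUCAG"
        region = make_region(up, "CCCAA")
        pu = pu_profile_region(region, flank=0)
        up_len = len(up)
        stem_offsets = [-up_len + 4 + k for k in range(6)]
        assert np.mean([pu[o] for o in stem_offsets]) < 0.5

    def test_flank_zero_equals_bare_window(self, structure_cohort):
        region = structure_cohort.regions[0]
        exon = next(e for e in structure_cohort.exons
                    if e.exon_id == region.exon_id)
        bare = pu_profile_region(region, flank=0)
        ctx0 = pu_profile_region(region, flank=0,
                                 genome=structure_cohort.genome, exon=exon)
        assert bare == ctx0

    def test_group_profile_of_identical_regions(self):
        region = make_region("GGGGAAAACCCCUUUCAG", "AAAAA")
        single = pu_profile_region(region, flank=0)
        prof = group_pu_profile([region, region], flank=0)
        for off, v in single.items():
            assert prof.mean_pu[off] == pytest.approx(v)
            assert prof.n[off] == 2

    def test_mixed_window_lengths_vary_coverage(self):
        a = make_region("A" * 20, "AAA")
        b = make_region("A" * 10, "AAA")
        prof = group_pu_profile([a, b], flank=0)
        assert prof.n[-15] == 1
        assert prof.n[-5] == 2

    def test_unstructured_group_mostly_unpaired(self, structure_cohort):
        """Pairing-poor cohort: mean PU >= 0.9 everywhere except the two
        planted AG dinucleotides (whose purines pair by construction)."""
        ups = structure_cohort.regions_by_group("up")
        prof = group_pu_profile(ups, flank=0)
        planted_ag = {-1, -2, -53, -54}
        for off, v in prof.mean_pu.items():
            if off not in planted_ag:
                assert v >= 0.9, (off, v)


class TestDeltaPU:
    def test_identical_groups_give_zero_delta_unit_p(self, structure_cohort):
        regs = structure_cohort.regions_by_group("up")[:8]
        res = delta_pu(regs, regs, flank=0)
        assert all(abs(d) < 1e-12 for d in res.delta.values())
        assert all(p == pytest.approx(1.0) for p in res.p.values())

    def test_group_swap_antisymmetry(self, structure_cohort):
        up = structure_cohort.regions_by_group("up")[:10]
        down = structure_cohort.regions_by_group("down")[:10]
        a = delta_pu(up, down, flank=0)
        b = delta_pu(down, up, flank=0)
        for off in a.offsets:
            assert a.delta[off] == pytest.approx(-b.delta[off], abs=1e-12)
            if off in a.p:
                assert a.p[off] == pytest.approx(b.p[off], abs=1e-12)

    def test_planted_structure_contrast_recovered(self, structure_cohort):
        """Hairpin-planted down group: positive delta PU and significant
        Wilcoxon p over the planted span, echoing the positional
        single-strandedness difference the pipeline is built to measure."""
        up = structure_cohort.regions_by_group("up")
        down = structure_cohort.regions_by_group("down")
        res = delta_pu(up, down, flank=0)
        span = [o for o in res.offsets if -50 <= o <= -25]
        assert np.mean([res.delta[o] for o in span]) > 0
        frac_sig = np.mean([res.p.get(o, 1.0) < 0.05 for o in span])
        assert frac_sig >= 0.8

    def test_bh_q_reported_alongside(self, structure_cohort):
        up = structure_cohort.regions_by_group("up")[:10]
        down = structure_cohort.regions_by_group("down")[:10]
        res = delta_pu(up, down, flank=0)
        assert set(res.q) == set(res.p)
        assert all(res.q[o] >= res.p[o] - 1e-12 for o in res.q)


class TestPUSubstring:
    def test_length_one_matches_positional_pu(self):
        seq = "GGGAAAACCCUU"
        res = partition_function(seq)
        pu = res.unpaired_probabilities()
        for i in (0, 3, 9):
            assert pu_substring(seq, i, 1) == pytest.approx(pu[i], abs=1e-9)

    def test_whole_sequence_unpaired_is_inverse_z(self):
        seq = "GGGAAAACCC"
        res = partition_function(seq)
        assert pu_substring(seq, 0, len(seq)) == pytest.approx(1.0 / res.Z)
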