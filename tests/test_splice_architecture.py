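import math

import numpy as np
import pytest

from acceptorkit.splice_architecture import (BranchPointCandidate, SiteModel,
                                             best_branch_point,
                                             count_purine_dinucleotides,
                                             default_bp_model, find_agez,
                                             load_site_model,
                                             ppt_for_branch_point,
                                             save_site_model,
                                             score_branch_points, score_site,
                                             site_pair_preference,
                                             train_site_model)
from conftest import make_region


def brute_force_agez(upstream: str) -> tuple[int, bool]:
    """Independent AGEZ oracle: scan every upstream dinucleotide."""
    up_len = len(upstream)
    best = None
    for i in range(up_len - 1):
        g_off = i + 1 - up_len            # offset of the G
        if upstream[i: i + 2] == "AG" and g_off <= -3:
            best = g_off                  # last hit is the most proximal
    if best is None:
        return up_len - 2, True
    return -best - 3, False


class TestAGEZ:
    @pytest.mark.parametrize("upstream, length, g_off, censored", [
        ("UAGUUUUUUUUCAG", 9, -12, False),
        ("UUUUUUUUUUUUAG", 12, None, True),
        ("AGAGAGAGAGAGAG", 0, -3, False),
    ])
    def test_hand_counted_examples(self, upstream, length, g_off, censored):
        res = find_agez(make_region(upstream))
        assert res.agez_length == length
        assert res.upstream_ag_offset == g_off
        assert res.censored is censored

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        for _ in range(1000):
            n = int(rng.integers(6, 60))
            upstream = "".join(rng.choice(list("ACGU"), size=n - 2)) + "AG"
            res = find_agez(make_region(upstream))
            exp_len, exp_cens = brute_force_agez(upstream)
            assert (res.agez_length, res.censored) == (exp_len, exp_cens)


class TestPurineDinucleotides:
    def test_run_of_g(self):
        marks = count_purine_dinucleotides(make_region("GGGGAG"), "GG")
        assert sum(marks.values()) == 3
        assert [o for o, v in marks.items() if v] == [-6, -5, -4]

    def test_absent_dinucleotide_all_zero(self):
        marks = count_purine_dinucleotides(make_region("ACUCAG"), "AG")
        assert set(marks.values()) <= {0, 1}
        # only the 3'ss AG itself exists and its G is at -1, not marked
        assert sum(marks.values()) == 0

    def test_group_frequency_dips_in_planted_zone(self, small_cohort):
        """AG occurrence frequency drops inside the planted AG-free zones."""
        ups = small_cohort.regions_by_group("up")
        per_offset = {}
        for r in ups:
            for off, v in count_purine_dinucleotides(r, "AG").items():
                per_offset.setdefault(off, []).append(v)
        freq = {o: np.mean(v) for o, v in per_offset.items()}
        inside = np.mean([freq[o] for o in range(-40, -4)])
        outside = np.mean([freq[o] for o in range(-100, -80)])
        assert inside < 0.02
        assert outside > 0.05


class TestSiteModel:
    def test_zero_pseudocount_indicator_columns(self):
        m = train_site_model(["UACUAAC", "UACUAAC"], pseudocount=0.0)
        assert np.allclose(m.columns.max(axis=1), 1.0)

    def test_positive_pseudocount_removes_zeros(self):
        m = train_site_model(["UACUAAC"], pseudocount=0.5)
        assert (m.columns > 0).all()

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            train_site_model(["ACGU", "ACG"])

    def test_sampling_recovery(self, rng):
        truth = np.array([[0.5, 0.2, 0.2, 0.1],
                          [0.1, 0.6, 0.1, 0.2],
                          [0.25, 0.25, 0.25, 0.25]])
        sites = ["".join("ACGU"[rng.choice(4, p=row)] for row in truth)
                 for _ in range(1000)]
        m = train_site_model(sites, pseudocount=0.0)
        assert np.abs(m.columns - truth).max() < 0.05

    def test_law_of_large_numbers_recovery(self, rng):
        truth = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])
        sites = ["".join("ACGU"[rng.choice(4, p=row)] for row in truth)
                 for _ in range(10_000)]
        m = train_site_model(sites, pseudocount=0.0)
        assert np.abs(m.columns - truth).max() < 0.02

    def test_round_trip_serialization(self, tmp_path):
        m = train_site_model(["UACUAAC", "CACUAAC"], site_type="bp",
                             pseudocount=0.3)
        path = tmp_path / "bp_model.tsv"
        save_site_model(m, path)
        loaded = load_site_model(path)
        assert loaded.site_type == "bp"
        assert np.allclose(loaded.columns, m.columns, atol=1e-9)
        assert np.allclose(loaded.background, m.background)


class TestScoreSite:
    def test_consensus_under_indicator_model_is_14_bits(self):
        m = train_site_model(["UACUAAC", "UACUAAC"], pseudocount=0.0)
        assert score_site("UACUAAC", m) == pytest.approx(7 * math.log2(4))

    def test_background_columns_score_zero(self):
        cols = np.full((5, 4), 0.25)
        m = SiteModel("3ss", cols, np.full(4, 0.25))
        assert score_site("ACGUA", m) == pytest.approx(0.0)

    def test_hand_arithmetic_with_pseudocount(self):
        # model trained on {"UACUAAC"} x2, pseudocount 0.1: observed base
        # prob (2+0.1)/2.4, others 0.1/2.4; last base U mismatches (C seen)
        m = train_site_model(["UACUAAC", "UACUAAC"], pseudocount=0.1)
        expected = 6 * math.log2((2.1 / 2.4) / 0.25) + \
            math.log2((0.1 / 2.4) / 0.25)
        assert score_site("UACUAAU", m) == pytest.approx(expected)

    def test_additive_in_positions(self):
        m = train_site_model(["UACUAAC", "CGCUUAC"], pseudocount=0.5)
        total = score_site("UGCUAAC", m)
        parts = sum(
            math.log2(m.columns[i, "ACGU".index(b)] / m.background["ACGU".index(b)])
            for i, b in enumerate("UGCUAAC"))
        assert total == pytest.approx(parts)

    def test_length_mismatch_and_n_rejected(self):
        m = train_site_model(["UACUAAC"], pseudocount=0.5)
        with pytest.raises(ValueError):
            score_site("UAC", m)
        with pytest.raises(ValueError):
            score_site("UACUANC", m)


class TestBranchPoints:
    def test_planted_motif_wins(self):
        up = "U" * 40 + "UACUAAC" + "U" * 20 + "UUUUCAG"
        region = make_region(up)
        best = best_branch_point(region)
        # branch A is the motif's 6th base
        motif_start = -len(up) + 40
        assert best.bp_offset == motif_start + 5

    def test_no_adenine_gives_empty_list(self):
        region = make_region("C" * 40 + "UUCAG")
        assert score_branch_points(region, search_range=(-9, -40)) == []

    def test_tie_broken_toward_proximal(self):
        up = "UACUAAC" + "CCCC" + "UACUAAC" + "CCCCCCCCCCCAG"
        region = make_region(up)
        cands = score_branch_points(region)
        top_two = [c for c in cands if c.window == "UACUAAC"]
        assert top_two[0].score == top_two[1].score
        assert top_two[0].bp_offset > top_two[1].bp_offset


class TestPPT:
    def _bp(self, off):
        return BranchPointCandidate(bp_offset=off, score=0.0, window="")

    def test_pure_pyrimidine_run(self):
        region = make_region("A" + "U" * 10 + "AG")
        res = ppt_for_branch_point(region, self._bp(-13))
        assert res.ppt_length == 10
        assert res.pyrimidine_fraction == 1.0

    def test_single_purine_absorbed(self):
        # exhaustive-scan oracle: score 8 pyr - 2*1 pur = 6 beats any 4-run
        region = make_region("A" + "UUUUAUUUU" + "AG")
        res = ppt_for_branch_point(region, self._bp(-12))
        assert res.ppt_length == 9
        assert res.ppt_start_offset == -11 and res.ppt_end_offset == -3

    def test_all_purine_gives_no_ppt(self):
        region = make_region("A" + "AAAAAAAA" + "AG")
        res = ppt_for_branch_point(region, self._bp(-11))
        assert res.ppt_length == 0
        assert res.ppt_start_offset is None

    def test_exhaustive_window_scan_oracle(self, rng):
        """Best window matches an independent exhaustive re-scan."""
        for _ in range(200):
            n = int(rng.integers(8, 30))
            mid = "".join(rng.choice(list("ACGU"), size=n))
            region = make_region("A" + mid + "AG")
            bp = self._bp(-(n + 3))
            res = ppt_for_branch_point(region, bp)
            best = None
            offsets = range(bp.bp_offset + 1, -2)
            for si, s in enumerate(offsets):
                for e in list(offsets)[si:]:
                    window = [region.base_at(o) for o in range(s, e + 1)]
                    length = e - s + 1
                    if length < 5:
                        continue
                    pyr = sum(b in "CU" for b in window)
                    if pyr / length < 0.6:
                        continue
                    score = pyr - 2 * (length - pyr)
                    key = (score, length, e)
                    if best is None or key > best:
                        best = key
            if best is None:
                assert res.ppt_length == 0
            else:
                assert (res.ppt_end_offset - res.ppt_start_offset + 1
                        == best[1])
                assert res.ppt_end_offset == best[2]

    def test_ppt_always_inside_bp_to_minus3(self, small_cohort):
        model = default_bp_model()
        for region in small_cohort.regions[:60]:
            bp = best_branch_point(region, model)
            res = ppt_for_branch_point(region, bp)
            if res.ppt_length:
                assert bp.bp_offset < res.ppt_start_offset
                assert res.ppt_end_offset <= -3


class TestSitePairPreference:
    def test_paper_counts(self):
        pairs = [(1.0, 0.0)] * 51 + [(0.0, 1.0)] * 87
        n_stronger, n_ties, n_total, p = site_pair_preference(pairs)
        assert (n_stronger, n_ties, n_total) == (51, 0, 138)
        assert round(p, 3) == 0.003

    def test_balanced_split_is_symmetric(self):
        pairs = [(1.0, 0.0)] * 5 + [(0.0, 1.0)] * 5
        assert site_pair_preference(pairs)[3] == pytest.approx(1.0)

    def test_extreme_split_closed_form(self):
        pairs = [(0.0, 1.0)] * 8
        assert site_pair_preference(pairs)[3] == pytest.approx(2 * 0.5 ** 8)

    def test_ties_reported_not_counted(self):
        pairs = [(1.0, 1.0)] * 3 + [(2.0, 1.0)] * 4
        n_stronger, n_ties, n_total, _ = site_pair_preference(pairs)
        assert (n_stronger, n_ties, n_total) == (4, 3, 7)
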