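"""Activity screen: grid search, the two standards, ranking, Wilcoxon."""

import numpy as np
import pytest

from methyltf import (
    ActivityCall,
    GridResult,
    MethylationTrack,
    ScreenConfig,
    classify,
    collect_sites,
    compare_distributions,
    derive_ratio_margin,
    grid_search,
    rank_and_report,
    run_screen,
    sweep_thresholds,
)


def _grid(tf="T", orientation="sense", C=(0.0,), S=(0.01,), z=((5.0,),)):
    C = np.asarray(C, float)
    S = np.asarray(S, float)
    z = np.asarray(z, float)
    ok = ~np.isnan(z)
    if ok.any():
        ci, sj = np.nonzero(ok)
        order = np.lexsort((S[sj], np.abs(C[ci]), -np.abs(z[ci, sj])))
        b = order[0]
        ext, cs, ss = z[ci[b], sj[b]], C[ci[b]], S[sj[b]]
    else:
        ext = cs = ss = np.nan
    return GridResult(tf, orientation, C, S, z, float(ext), float(cs), float(ss))


class TestClassify:
    def test_thirteen_percent_gain_is_active(self):
        call = classify(
            "T", "t", 10.0, _grid(z=((11.3,),)), _grid(orientation="antisense", z=((9.0,),)),
            ratio_margin=0.10,
        )
        assert call.active and call.direction == "positive"
        assert call.ratio == pytest.approx(1.13)

    def test_five_percent_gain_is_inactive(self):
        call = classify(
            "T", "t", 10.0, _grid(z=((10.5,),)), _grid(orientation="antisense", z=((9.0,),)),
            ratio_margin=0.10,
        )
        assert not call.active

    def test_antisense_exceedance_vetoes_regardless_of_gain(self):
        anti = _grid(orientation="antisense", C=(-1.0, 1.0), z=((3.0,), (10.4,)))
        call = classify("T", "t", 10.0, _grid(z=((14.0,),)), anti, ratio_margin=0.10)
        assert not call.active
        assert call.max_abs_z_m_q == pytest.approx(10.4)

    def test_antisense_reproducing_baseline_does_not_veto(self):
        # a saturated antisense corner reproduces Z_m_o exactly; that is
        # the no-effect limit, not evidence for the wrong-signed model
        anti = _grid(orientation="antisense", C=(-2.0, 0.0), z=((10.0,), (4.0,)))
        call = classify("T", "t", 10.0, _grid(z=((11.5,),)), anti, ratio_margin=0.10)
        assert call.active

    def test_negative_direction_and_sign_flip_flag(self):
        call = classify(
            "T", "t", -4.0, _grid(z=((-5.0,),)), _grid(orientation="antisense", z=((2.0,),)),
            ratio_margin=0.10,
        )
        assert call.active and call.direction == "negative" and not call.sign_flip
        flipped = classify(
            "T", "t", -4.0, _grid(z=((5.0,),)), _grid(orientation="antisense", z=((2.0,),)),
            ratio_margin=0.10,
        )
        assert flipped.sign_flip


class TestRatioMargin:
    def test_degenerate_ratios_floor_at_zero(self):
        assert derive_ratio_margin([1.0] * 12) == 0.0

    def test_hand_computed_percentile(self):
        ratios = [1.00, 1.01, 1.02, 1.03, 1.04, 1.05, 1.06, 1.07, 1.08, 1.09]
        # linear interpolation: position 0.9*(10-1) = 8.1 -> 1.081
        assert derive_ratio_margin(ratios, percentile=0.9) == pytest.approx(0.081)

    def test_few_ratios_fall_back_to_default(self):
        assert derive_ratio_margin([1.5] * 5) == 0.10


class TestCompareDistributions:
    def test_identical_lists_degenerate(self):
        rep = compare_distributions([1.0] * 8, [1.0] * 8)
        assert rep.degenerate and rep.pvalue == 1.0

    def test_uniform_shift_is_significant(self):
        zo = list(np.linspace(2, 8, 20))
        rep = compare_distributions(zo, [z + 1.0 for z in zo])
        assert rep.pvalue < 1e-4 and rep.n == 20

    def test_type_one_error_is_calibrated(self, rng):
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(0, 1, 20)
            b = a + rng.normal(0, 1, 20)
            if compare_distributions(a, b).pvalue < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sim <= 0.08

    def test_rejects_short_lists(self):
        with pytest.raises(ValueError):
            compare_distributions([1, 2, 3], [1, 2, 3])


def _call(tf_id, name, zo, zp, active=True):
    return ActivityCall(
        tf_id, name, zo, zp, 0.0, 0.01, abs(zo) - 1, abs(zp / zo), active,
        "positive" if zo >= 0 else "negative",
    )


class TestRankAndReport:
    def test_sorting_and_direction_split(self):
        calls = [
            _call("a", "A", 9.0, 10.5),
            _call("b", "B", 10.0, 13.9),
            _call("c", "C", 9.5, 11.7),
            _call("d", "D", -2.9, -3.4),
            _call("e", "E", 4.0, 4.1, active=False),
        ]
        pos, neg = rank_and_report(calls)
        assert list(pos["z_m_p"]) == [13.9, 11.7, 10.5]
        assert list(pos["rank"]) == [1, 2, 3]
        assert list(neg["tf_id"]) == ["d"]
        assert "e" not in set(pos["tf_id"])

    def test_dedup_keeps_strongest_matrix_per_name(self):
        calls = [_call("m1", "SAME", 9.0, 10.0), _call("m2", "SAME", 9.0, 12.0)]
        pos, _ = rank_and_report(calls, dedup=True)
        assert list(pos["tf_id"]) == ["m2"]
        pos_all, _ = rank_and_report(calls, dedup=False)
        assert len(pos_all) == 2


class TestGridSearch:
    def test_single_cell_grid_extreme_is_that_cell(self, small_sim, small_expr):
        table = collect_sites(
            small_sim.pwms[0], small_sim.promoters, small_sim.track, top_k=30
        )
        g = grid_search(table, small_expr, C_grid=[0.3], S_grid=[0.05], k_min=5)
        assert g.z_m.shape == (1, 1)
        assert g.extreme_z == g.z_m[0, 0]
        assert (g.C_star, g.S_star) == (0.3, 0.05)

    def test_saturating_sense_cells_reproduce_match_z(self, small_sim, small_expr):
        zero_track = MethylationTrack(
            {g: np.zeros(len(small_sim.promoters[g])) for g in small_sim.promoters.gene_ids},
            small_sim.promoters,
        )
        table = collect_sites(small_sim.pwms[0], small_sim.promoters, zero_track, top_k=30)
        zo = sweep_thresholds(
            (table.gene_ids, table.match_scores()), small_expr, k_min=5
        ).z_m
        g = grid_search(
            table, small_expr, C_grid=[0.5, 1.0, 2.0], S_grid=[0.01], k_min=5
        )
        np.testing.assert_allclose(g.z_m[:, 0], zo, atol=1e-6)

    def test_rerun_is_bit_identical(self, small_sim, small_expr):
        table = collect_sites(small_sim.pwms[0], small_sim.promoters, small_sim.track, top_k=30)
        kwargs = dict(C_grid=np.arange(-1, 1.01, 0.25), S_grid=[0.01, 0.1], k_min=5)
        g1 = grid_search(table, small_expr, **kwargs)
        g2 = grid_search(table, small_expr, **kwargs)
        np.testing.assert_array_equal(g1.z_m, g2.z_m)
        assert (g1.C_star, g1.S_star, g1.extreme_z) == (g2.C_star, g2.S_star, g2.extreme_z)


class TestRunScreen:
    def test_small_planted_screen_end_to_end(self, small_sim, small_expr):
        config = ScreenConfig(
            C_grid=np.round(np.arange(-1.0, 1.01, 0.25), 10),
            S_grid=[0.01, 0.1],
            k_min=5,
            top_k=30,
        )
        res = run_screen(
            small_sim.pwms, small_sim.promoters, small_sim.track, small_expr, config
        )
        assert len(res.calls) == len(small_sim.pwms)
        planted = next(c for c in res.calls if c.tf_id == small_sim.pwms[0].tf_id)
        # the planted activator's methylation-aware extreme must beat its
        # sequence-only Z
        assert planted.z_m_o > 0
        assert abs(planted.z_m_p) > abs(planted.z_m_o)
        assert res.margin == 0.10  # fixed default
        for tf_id, (sense, anti) in res.grids.items():
            assert sense.z_m.shape == (9, 2)
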