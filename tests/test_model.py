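"""Sigmoid effect model, site methylation summaries, binding scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methyltf import (
    MethylationTrack,
    ModelParams,
    Promoter,
    PromoterSet,
    PWM,
    ValidationError,
    binding_matrix,
    binding_score,
    collect_sites,
    effect_antisense,
    effect_sense,
    match_values,
    scan_all,
    site_methylation,
)

finite = st.floats(min_value=-4, max_value=4, allow_nan=False)
steep = st.floats(min_value=1e-3, max_value=2.0, allow_nan=False)


class TestEffectFunctions:
    def test_midpoint_is_half(self):
        for c, s in [(0.0, 0.1), (0.25, 0.01), (-1.7, 1.0)]:
            assert effect_sense(c, c, s) == pytest.approx(0.5)
            assert effect_antisense(c, c, s) == pytest.approx(0.5)

    def test_saturation(self):
        assert effect_sense(2.0, 0.0, 0.1) < 1e-8
        assert effect_antisense(-2.0, 0.0, 0.1) < 1e-8
        assert effect_sense(-2.0, 0.0, 0.1) > 1 - 1e-8

    def test_near_step_at_small_steepness(self):
        # one steepness unit away from the center: expit(+-1)
        lo = effect_sense(0.24, 0.25, 0.01)
        hi = effect_sense(0.26, 0.25, 0.01)
        assert hi < 0.5 < lo
        assert lo == pytest.approx(0.7310585786300049)
        assert hi == pytest.approx(0.2689414213699951)
        # three steepness units out the transition is nearly complete
        assert effect_sense(0.22, 0.25, 0.01) - effect_sense(0.28, 0.25, 0.01) > 0.9

    def test_overflow_safe_far_from_center(self):
        # exponent magnitude ~400: must saturate without warnings or NaN
        with np.errstate(all="raise"):
            v0 = effect_sense(2.0, -2.0, 0.01)
            v1 = effect_sense(-2.0, 2.0, 0.01)
        assert v0 < 1e-150 and v1 == 1.0

    @given(M=finite, C=finite, S=steep)
    @settings(max_examples=300, derandomize=True)
    def test_mirror_identity(self, M, C, S):
        assert effect_sense(M, C, S) + effect_antisense(M, C, S) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(C=finite, S=steep, data=st.data())
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_methylation(self, C, S, data):
        m1 = data.draw(finite)
        m2 = data.draw(finite)
        lo, hi = min(m1, m2), max(m1, m2)
        assert effect_sense(hi, C, S) <= effect_sense(lo, C, S)
        assert effect_antisense(hi, C, S) >= effect_antisense(lo, C, S)
        # strict in the non-saturated band, given a resolvable gap
        if abs((lo - C) / S) < 30 and abs((hi - C) / S) < 30 and (hi - lo) / S > 1e-9:
            assert effect_sense(hi, C, S) < effect_sense(lo, C, S)

    def test_invalid_steepness_rejected(self):
        with pytest.raises(ValidationError):
            ModelParams(center=0.0, steepness=0.0)


class TestSiteMethylation:
    def _track(self, vec):
        n = len(vec)
        ps = PromoterSet([Promoter("g", "A" * n)])
        return MethylationTrack({"g": np.asarray(vec, dtype=float)}, ps)

    def test_constant_window(self):
        m, frac = site_methylation(self._track([0.7] * 6), "g", 1, 4)
        assert m == pytest.approx(0.7) and frac == 1.0

    def test_mean_of_present_values(self):
        m, frac = site_methylation(self._track([0.2, 0.4, np.nan]), "g", 0, 3)
        assert m == pytest.approx(0.3)
        assert frac == pytest.approx(2 / 3)

    def test_fully_missing_window(self):
        m, frac = site_methylation(self._track([np.nan] * 4), "g", 0, 4)
        assert np.isnan(m) and frac == 0.0

    def test_out_of_bounds_is_an_error(self):
        with pytest.raises(ValidationError):
            site_methylation(self._track([0.1] * 4), "g", 2, 4)


def _pair(seq, meth):
    ps = PromoterSet([Promoter("g", seq)])
    track = MethylationTrack({"g": np.asarray(meth, dtype=float)}, ps)
    return ps, track


class TestBindingScore:
    A_FAVOR = PWM("T", "t", np.array([[1, 0, 0, 0]] * 2, dtype=float))

    def test_unsaturated_regime_reduces_to_match_score(self):
        ps, track = _pair("AAAA", [0.0] * 4)
        sites = match_values(self.A_FAVOR, ps["g"])
        params = ModelParams(center=-2.0, steepness=0.01, orientation="sense")
        # C = -2 means everything at methylation 0 is fully suppressed;
        # the opposite corner leaves scores untouched
        b, _ = binding_score(sites, track, params)
        assert b == pytest.approx(0.0, abs=1e-6)
        params = ModelParams(center=2.0, steepness=0.01, orientation="sense")
        b, arg = binding_score(sites, track, params)
        assert b == pytest.approx(2.0, abs=1e-6)

    def test_argmax_is_over_product_not_match_value(self):
        # two sites A = [5, 4] with methylation [2, -2]: the better
        # sequence match is wiped out, the weaker site must win
        pwm = PWM("T", "t", np.array([[5, 0, 0, 0]], dtype=float))
        ps, track = _pair("AG", [2.0, -2.0])
        sites = match_values(pwm, ps["g"], strands="sense")
        sites.match_value[:] = [5.0, 4.0]
        params = ModelParams(center=0.0, steepness=0.01, orientation="sense")
        b, arg = binding_score(sites, track, params)
        assert b == pytest.approx(4.0, abs=1e-6)
        assert arg[0] == 1

    def test_missing_methylation_neutral_vs_skip(self):
        ps, track = _pair("AA", [np.nan, np.nan])
        sites = match_values(self.A_FAVOR, ps["g"], strands="sense")
        params = ModelParams(center=-2.0, steepness=0.01, orientation="sense")
        b, _ = binding_score(sites, track, params, missing_policy="neutral")
        assert b == pytest.approx(2.0)
        b, arg = binding_score(sites, track, params, missing_policy="skip")
        assert b == float("-inf") and arg is None

    def test_binding_never_exceeds_match_under_neutral(self, rng):
        pwm = PWM("T", "t", rng.random((3, 4)))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        meth = rng.uniform(-2, 2, 40)
        meth[rng.random(40) < 0.2] = np.nan
        ps, track = _pair(seq, meth)
        sites = match_values(pwm, ps["g"])
        from methyltf import match_score

        ms, _ = match_score(sites)
        for c in (-1.0, 0.0, 1.0):
            for s in (0.01, 0.1, 1.0):
                for orient in ("sense", "antisense"):
                    b, _ = binding_score(
                        sites, track, ModelParams(c, s, orient), "neutral"
                    )
                    assert b <= ms + 1e-12


class TestBindingMatrix:
    def _instance(self, rng, n_genes=6, n=30):
        proms, meth = [], {}
        for i in range(n_genes):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
            proms.append(Promoter(f"g{i}", seq))
            meth[f"g{i}"] = rng.uniform(-2, 2, n)
        ps = PromoterSet(proms)
        track = MethylationTrack(meth, ps)
        pwms = [PWM(f"T{t}", f"t{t}", rng.random((4, 4))) for t in range(3)]
        return pwms, ps, track

    def test_saturating_params_reduce_to_match_matrix(self, rng):
        pwms, ps, track = self._instance(rng)
        tables = [collect_sites(p, ps, track, top_k=100) for p in pwms]
        match = scan_all(pwms, ps)
        up = binding_matrix(tables, ModelParams(30.0, 0.01, "sense"))
        np.testing.assert_allclose(up.values, match.values, atol=1e-6)
        down = binding_matrix(tables, ModelParams(-30.0, 0.01, "sense"))
        np.testing.assert_allclose(down.values, 0.0, atol=1e-6)

    def test_matches_per_pair_binding_score(self, rng):
        pwms, ps, track = self._instance(rng)
        tables = [collect_sites(p, ps, track, top_k=100) for p in pwms]
        params = ModelParams(0.3, 0.1, "sense")
        mat = binding_matrix(tables, params)
        for t, pwm in enumerate(pwms):
            for g, gid in enumerate(ps.gene_ids):
                b, arg = binding_score(match_values(pwm, ps[gid]), track, params)
                assert mat.values[t, g] == pytest.approx(b)
                assert mat.argmax_site[t, g] == arg[0]
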