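"""Peak-caller checks: recombination models against a Monte-Carlo meiosis
oracle, the frequency-to-G' mapping and its inversion, BIC model selection,
refinement and support intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import texqtl.peaks as pk
from texqtl.power import _calibration_genome, simulate_freq_chromosome


def mc_three_locus_oracle(p1, p2, d1_cm, d2_cm, rng, n=200_000):
    """Meiosis + acceptance-resampling oracle for the three-locus expected
    marker frequency: simulate unselected gametes (two Bernoulli crossover
    events), then reweight by independent per-QTL selection factors chosen
    to hit the target marginals.

    Returns (frequency estimate, Monte-Carlo SE).
    """
    from scipy.optimize import fsolve

    r1 = pk.recomb_fraction(d1_cm)
    r2 = pk.recomb_fraction(d2_cm)
    q1 = rng.random(n) < 0.5
    m = q1 ^ (rng.random(n) < r1)
    q2 = m ^ (rng.random(n) < r2)

    def moments(log_ab):
        a, b = np.exp(log_ab)
        w = np.where(q1, a, 1.0) * np.where(q2, b, 1.0)
        tot = w.sum()
        return [(w * q1).sum() / tot - p1, (w * q2).sum() / tot - p2]

    log_ab = fsolve(moments, [0.0, 0.0], xtol=1e-12)
    a, b = np.exp(log_ab)
    w = np.where(q1, a, 1.0) * np.where(q2, b, 1.0)
    est = float((w * m).sum() / w.sum())
    ess = w.sum() ** 2 / (w**2).sum()
    return est, math.sqrt(0.25 / ess)


class TestRecombinationModels:
    def test_haldane_closed_forms(self):
        assert pk.recomb_fraction(0.0) == 0.0
        assert pk.recomb_fraction(10.0) == pytest.approx(0.0906346, abs=1e-6)
        assert pk.recomb_fraction(1e6) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            pk.recomb_fraction(-1.0)

    def test_two_locus_limits(self):
        assert pk.expected_af_two_locus(0.8, 0.0) == pytest.approx(0.8)
        assert pk.expected_af_two_locus(0.8, 0.5) == pytest.approx(0.5)
        assert pk.expected_af_two_locus(0.6, 0.1) == pytest.approx(0.58)

    def test_three_locus_degenerate_cases(self):
        # marker coincides with both flanks
        assert pk.expected_af_three_locus(0.7, 0.7, 0.0, 0.0) == pytest.approx(0.7)
        # unlinked marker
        assert pk.expected_af_three_locus(0.7, 0.6, 0.5, 0.5) == pytest.approx(0.5)
        # unselected flanks leave the marker unselected
        assert pk.expected_af_three_locus(
            0.5, 0.5, 0.1, 0.2) == pytest.approx(0.5)

    @pytest.mark.parametrize("p1", [0.55, 0.6, 0.8])
    @pytest.mark.parametrize("p2", [0.55, 0.7])
    @pytest.mark.parametrize("d1,d2", [(2.0, 8.0), (5.0, 5.0), (12.0, 4.0)])
    def test_three_locus_matches_meiosis_oracle(self, p1, p2, d1, d2, rng):
        r1, r2 = pk.recomb_fraction(d1), pk.recomb_fraction(d2)
        analytic = float(pk.expected_af_three_locus(p1, p2, r1, r2))
        mc, se = mc_three_locus_oracle(p1, p2, d1, d2, rng)
        assert analytic == pytest.approx(mc, abs=3.5 * se)

    def test_plackett_reduces_to_unselected_ld(self):
        # at p1 = p2 = 0.5 the joint must equal the F2 haplotype law
        for r in (0.05, 0.2, 0.4):
            h = pk._plackett_joint(0.5, 0.5, r)
            assert h == pytest.approx((1 - r) / 2, rel=1e-9)


@pytest.fixture(scope="module")
def ctx(calib_markers):
    return pk.GPrimeContext(calib_markers, 5000, "one_tailed", 36.0)


class TestFrequencyGprimeMapping:
    def test_no_divergence_maps_to_zero(self, ctx):
        assert ctx.af_to_gprime(0.5) == pytest.approx(0.0, abs=1e-9)

    def test_isolated_marker_expected_g(self):
        # single-marker chromosome: G' equals the raw expected G of the
        # 2x2 expected-count table; value computed independently below
        lone = pk.GPrimeContext(np.array([50.0]), 5000, "one_tailed", 36.0)
        expected = 2 * (3000 * math.log(3000 / 2750)
                        + 2000 * math.log(2000 / 2250)
                        + 2500 * math.log(2500 / 2750)
                        + 2500 * math.log(2500 / 2250))
        assert lone.af_to_gprime(0.6, 0) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_frequency(self, ctx):
        ps = np.linspace(0.5, 0.99, 50)
        vals = [ctx.af_to_gprime(p) for p in ps]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("p", [0.55, 0.7, 0.9])
    def test_round_trip_inversion(self, ctx, p):
        assert ctx.gprime_to_af(ctx.af_to_gprime(p)) == pytest.approx(p, abs=1e-5)

    def test_above_maximum_clamps(self, ctx):
        top = ctx.af_to_gprime(1.0)
        assert ctx.gprime_to_af(top * 1.01) == 1.0

    def test_two_tailed_stronger_than_one_tailed(self, calib_markers):
        two = pk.GPrimeContext(calib_markers, 5000, "two_tailed", 36.0)
        one = pk.GPrimeContext(calib_markers, 5000, "one_tailed", 36.0)
        assert two.af_to_gprime(0.6) > one.af_to_gprime(0.6)


class TestExpectedCurve:
    def test_zero_qtl_model_is_flat_zero(self, ctx):
        curve = ctx.expected_curve(np.array([], dtype=int), np.array([]))
        assert np.allclose(curve, 0.0)

    def test_single_qtl_curve_peaks_at_qtl(self, ctx):
        curve = ctx.expected_curve(np.array([250]), np.array([0.6]))
        assert int(np.argmax(curve)) == 250
        # decays monotonically on each side
        assert np.all(np.diff(curve[:251]) >= -1e-9)
        assert np.all(np.diff(curve[250:]) <= 1e-9)
        assert np.all(curve >= 0)

    def test_batch_matches_scalar(self, ctx):
        idx = np.array([100, 300])
        F = np.array([[0.6, 0.7], [0.55, 0.62]])
        batch = ctx.expected_curve(idx, F)
        for k in range(2):
            assert np.allclose(batch[k], ctx.expected_curve(idx, F[k]))


class TestFitStatistics:
    def test_rmse_closed_forms(self):
        assert pk.rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert pk.rmse([1, 2, 3], [0, 1, 2]) == pytest.approx(1.0)
        assert pk.rmse([1, 2, 3], [1, 1, 1]) == pytest.approx(math.sqrt(5 / 3))
        with pytest.raises(ValueError):
            pk.rmse([1, 2], [1])

    def test_bic_closed_forms(self):
        assert pk.bic(1.0, 100, 3) == pytest.approx(6 * math.log(100))
        assert pk.bic(1.0, 100, 0) == 0.0
        # removing one QTL at unchanged RMSE lowers BIC by exactly 2 ln n
        n = 137
        assert pk.bic(0.7, n, 4) - pk.bic(0.7, n, 3) == pytest.approx(
            2 * math.log(n))

    def test_bic_floors_zero_rmse(self):
        assert np.isfinite(pk.bic(0.0, 10, 1))

    def test_interval_multipliers_n100(self):
        lo, hi = pk.rmse_interval_multipliers(100, 0.05)
        assert lo == pytest.approx(math.sqrt(100 / stats.chi2.ppf(0.975, 100)))
        assert lo == pytest.approx(0.8785, abs=2e-4)
        assert hi == pytest.approx(1.1608, abs=2e-4)

    def test_interval_multipliers_concentrate(self):
        lo, hi = pk.rmse_interval_multipliers(10**6, 0.05)
        assert lo == pytest.approx(1.0, abs=3e-3)
        assert hi == pytest.approx(1.0, abs=3e-3)


class TestCandidates:
    def test_unimodal_curve_contains_argmax(self, calib_markers):
        g = np.exp(-((calib_markers - 50) ** 2) / 200)
        cand = pk.find_candidates(g, calib_markers, 36.0)
        assert int(np.argmax(g)) in cand

    def test_monotone_curve_falls_back_to_argmax(self):
        pos = np.arange(100, dtype=float)
        g = np.linspace(0, 10, 100)
        cand = pk.find_candidates(g, pos, 36.0)
        assert cand.size >= 1

    def test_min_separation_dedup(self, calib_markers):
        g = np.exp(-((calib_markers - 50) ** 2) / 200)
        cand = pk.find_candidates(g, calib_markers, 36.0, min_separation_cm=18.0)
        d = np.diff(np.sort(calib_markers[cand]))
        assert np.all(d >= 18.0) if d.size else True

    def test_two_bumps_far_apart_both_found(self, calib_markers, rng):
        # candidate maxima of a two-QTL curve sit a few cM inside the true
        # loci (the between-QTL region is lifted by linkage to both
        # flanks); each bump must still seed a candidate nearby
        hits = 0
        runs = 25
        for _ in range(runs):
            prof = simulate_freq_chromosome(calib_markers, [30.0, 70.0],
                                            [0.6, 0.6], 5000, 36.0, rng)
            cand = pk.find_candidates(prof["Gprime"].to_numpy(),
                                      calib_markers, 36.0)
            cpos = calib_markers[cand]
            if (np.abs(cpos - 30).min() <= 10) and (np.abs(cpos - 70).min() <= 10):
                hits += 1
        assert hits >= runs - 2


@pytest.fixture(scope="module")
def single_qtl_case(calib_markers):
    rng = np.random.default_rng(99)
    prof = simulate_freq_chromosome(calib_markers, [50.0], [0.6],
                                    5000, 36.0, rng)
    ctx = pk.GPrimeContext(calib_markers, 5000, "one_tailed", 36.0)
    return ctx, prof


class TestModelSelection:
    def test_elimination_never_raises_bic(self, single_qtl_case):
        ctx, prof = single_qtl_case
        obs = prof["Gprime"].to_numpy()
        m0 = pk.initial_model(ctx, obs, prof["af_diff"].to_numpy())
        m1 = pk.backward_eliminate(ctx, obs, m0)
        assert m1.bic <= m0.bic
        # fixed point: eliminating again changes nothing
        m2 = pk.backward_eliminate(ctx, obs, m1)
        assert np.array_equal(m1.idx, m2.idx)

    def test_refinement_never_raises_rmse(self, single_qtl_case):
        ctx, prof = single_qtl_case
        obs = prof["Gprime"].to_numpy()
        m0 = pk.backward_eliminate(
            ctx, obs, pk.initial_model(ctx, obs, prof["af_diff"].to_numpy()))
        m1 = pk.refine(ctx, obs, m0)
        assert m1.rmse <= m0.rmse + 1e-12
        m2 = pk.refine(ctx, obs, m1)
        assert m2.rmse == pytest.approx(m1.rmse)

    def test_refinement_recovers_displaced_position(self, calib_markers):
        # start the model 5 cM off the true QTL; refinement comes home
        rng = np.random.default_rng(7)
        recovered = 0
        runs = 20
        ctx = pk.GPrimeContext(calib_markers, 5000, "one_tailed", 36.0)
        true_idx = int(np.argmin(np.abs(calib_markers - 50.0)))
        for _ in range(runs):
            prof = simulate_freq_chromosome(calib_markers, [50.0], [0.6],
                                            5000, 36.0, rng)
            obs = prof["Gprime"].to_numpy()
            start = pk._evaluate(ctx, obs, np.array([true_idx + 25]),
                                 np.array([0.6]))
            ref = pk.refine(ctx, obs, start)
            if abs(int(ref.idx[0]) - true_idx) <= 5:
                recovered += 1
        assert recovered >= runs - 2

    def test_peaks_lie_on_markers_and_within_candidates(self, single_qtl_case):
        ctx, prof = single_qtl_case
        obs = prof["Gprime"].to_numpy()
        cand = pk.find_candidates(obs, ctx.pos, 36.0)
        final = pk.select_model(ctx, obs, prof["af_diff"].to_numpy())
        assert final.m <= cand.size
        assert np.all((final.idx >= 0) & (final.idx < ctx.n))

    def test_select_model_is_deterministic(self, single_qtl_case):
        ctx, prof = single_qtl_case
        obs = prof["Gprime"].to_numpy()
        a = pk.select_model(ctx, obs, prof["af_diff"].to_numpy())
        b = pk.select_model(ctx, obs, prof["af_diff"].to_numpy())
        assert np.array_equal(a.idx, b.idx)
        assert np.allclose(a.freqs, b.freqs)


class TestSupportInterval:
    def test_interval_contains_peak(self, calib_markers):
        rng = np.random.default_rng(13)
        prof = simulate_freq_chromosome(calib_markers, [50.0], [0.6],
                                        5000, 36.0, rng)
        ctx = pk.GPrimeContext(calib_markers, 5000, "one_tailed", 36.0)
        obs = prof["Gprime"].to_numpy()
        model = pk.select_model(ctx, obs, prof["af_diff"].to_numpy())
        lo, hi, clipped = pk.support_interval(ctx, obs, model, 0)
        assert lo <= model.idx[0] <= hi
        assert not clipped

    def test_empty_model_rejected(self, calib_markers):
        ctx = pk.GPrimeContext(calib_markers, 5000, "one_tailed", 36.0)
        empty = pk.ChromosomeModel(np.array([], int), np.array([]), 1.0, 0.0,
                                   np.zeros(ctx.n))
        with pytest.raises(ValueError):
            pk.support_interval(ctx, np.zeros(ctx.n), empty, 0)


class TestCallQTL:
    def test_null_profile_yields_no_qtl(self, calib_markers, rng):
        prof = simulate_freq_chromosome(calib_markers, [], [], 5000, 36.0, rng)
        fits = pk.call_qtl(prof, "one_tailed", 5000, 36.0, gprime_threshold=5.0)
        assert fits == []

    def test_two_qtl_forty_cm_apart_resolved(self, calib_markers):
        rng = np.random.default_rng(31)
        two = 0
        runs = 15
        for _ in range(runs):
            prof = simulate_freq_chromosome(calib_markers, [30.0, 70.0],
                                            [0.6, 0.6], 5000, 36.0, rng)
            fits = pk.call_qtl(prof, "one_tailed", 5000, 36.0,
                               gprime_threshold=2.0)
            if sum(f.m for f in fits) == 2:
                two += 1
        assert two >= runs - 2

    def test_two_qtl_eight_cm_apart_merge(self, calib_markers):
        rng = np.random.default_rng(37)
        merged = 0
        runs = 10
        for _ in range(runs):
            prof = simulate_freq_chromosome(calib_markers, [46.0, 54.0],
                                            [0.6, 0.6], 5000, 36.0, rng)
            fits = pk.call_qtl(prof, "one_tailed", 5000, 36.0,
                               gprime_threshold=2.0)
            if sum(f.m for f in fits) == 1:
                merged += 1
        assert merged >= runs - 1
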