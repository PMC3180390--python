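"""Monte-Carlo shift significance and FPR calibration."""

import numpy as np
import pytest

from dtwshift.heterosim import NoiseSpec, constant_shift, make_pair, sine_model
from dtwshift.significance import (
    CountDistributions,
    NoiseModel,
    SignificanceConfig,
    build_null_model,
    choose_threshold,
    estimate_fpr,
    fpr_curve,
    pointwise_pvalues,
    run_gene_significance,
    simulate_zero_shift_pair,
)

from conftest import make_raw


class TestNoiseModel:
    def test_noiseless_fit_gives_zero_sd(self):
        t = np.linspace(0, 5, 20)
        model, noise = build_null_model(make_raw(t, 2 * t + 1), df=2)
        assert noise.sd < 1e-6

    def test_sd_consistent_with_injected_noise(self, rng):
        t = np.linspace(0, 10, 200)
        y = np.sin(t) + rng.normal(0, 0.3, t.size)
        _, noise = build_null_model(make_raw(t, y), df="gcv")
        assert abs(noise.sd - 0.3) / 0.3 < 0.15

    def test_residual_mean_retained(self):
        r = np.array([0.1, 0.2, 0.3, 0.15])
        nm = NoiseModel.from_residuals(r)
        assert nm.mean == pytest.approx(np.mean(r))
        assert nm.sd == pytest.approx(np.std(r, ddof=1))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(mean=0.0, sd=-1.0)


class TestSimulateZeroShiftPair:
    def test_zero_sd_lies_on_model_curve(self, noisy_cubic_series, rng):
        model, _ = build_null_model(noisy_cubic_series, df=4)
        quiet = NoiseModel(mean=0.0, sd=0.0)
        t = noisy_cubic_series.ages
        a, b = simulate_zero_shift_pair(model, quiet, t, t, rng)
        np.testing.assert_allclose(a.values, model.predict(t))
        np.testing.assert_allclose(b.values, model.predict(t))

    def test_rng_contract(self, noisy_cubic_series):
        model, noise = build_null_model(noisy_cubic_series, df=4)
        t = noisy_cubic_series.ages
        a1, b1 = simulate_zero_shift_pair(model, noise, t, t, np.random.default_rng(5))
        a2, b2 = simulate_zero_shift_pair(model, noise, t, t, np.random.default_rng(5))
        a3, _ = simulate_zero_shift_pair(model, noise, t, t, np.random.default_rng(6))
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(b1.values, b2.values)
        assert not np.array_equal(a1.values, a3.values)

    def test_times_outside_domain_error(self, noisy_cubic_series, rng):
        model, noise = build_null_model(noisy_cubic_series, df=4)
        bad = model.domain[1] + np.arange(1.0, 6.0)
        with pytest.raises(ValueError, match="domain"):
            simulate_zero_shift_pair(model, noise, bad, bad, rng)


class TestPointwisePvalues:
    def test_arithmetic(self):
        real = np.array([0.0, 1.0, 5.0])
        sims = np.array([[0.5, 1.0, 1.0], [0.2, 2.0, 2.0], [0.0, 0.5, 3.0], [1.0, 1.5, 4.0]])
        p = pointwise_pvalues(real, sims)
        # zero real shift: every |sim| >= 0 -> p = 1; real above all sims -> 0
        np.testing.assert_allclose(p, [1.0, 3 / 4, 0.0])

    def test_permutation_invariance(self, rng):
        real = rng.normal(size=10)
        sims = rng.normal(size=(50, 10))
        p1 = pointwise_pvalues(real, sims)
        p2 = pointwise_pvalues(real, sims[rng.permutation(50)])
        np.testing.assert_array_equal(p1, p2)

    def test_correction_variant(self):
        real = np.array([10.0])
        sims = np.zeros((99, 1))
        assert pointwise_pvalues(real, sims)[0] == 0.0
        assert pointwise_pvalues(real, sims, correction=True)[0] == pytest.approx(0.01)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            pointwise_pvalues(rng.normal(size=5), rng.normal(size=(10, 6)))


class TestEstimateFpr:
    def _dists(self):
        real = np.array([0, 1, 2, 5, 8, 9, 10, 3])
        null = np.array([[0, 1], [1, 0], [2, 1], [0, 3], [1, 1], [0, 0], [2, 2], [1, 4]])
        return CountDistributions(real, null)

    def test_c_zero_is_one(self):
        assert estimate_fpr(self._dists(), 0) == 1.0

    def test_zero_when_null_below_threshold(self):
        assert estimate_fpr(self._dists(), 5) == 0.0

    def test_empty_real_tail_errors(self):
        with pytest.raises(ValueError, match="no genes at threshold"):
            estimate_fpr(self._dists(), 11)

    def test_reproduces_published_tail_ratio(self):
        """Given the tail pair the ratio definition implies, FPR ~ 10.7%."""
        n_genes = 1183
        real = np.zeros(n_genes, dtype=int)
        real[:482] = 7  # 482/1183 genes at or above the count threshold
        null = np.zeros((n_genes, 1), dtype=int)
        k = int(round(0.0436 * n_genes))
        null[:k, 0] = 7
        fpr = estimate_fpr(CountDistributions(real, null), 7)
        assert fpr == pytest.approx(0.107, abs=0.002)

    def test_choose_threshold_matches_direct_scan(self, rng):
        real = rng.integers(0, 15, size=200)
        null = rng.integers(0, 6, size=(200, 10))
        dists = CountDistributions(real, null)
        target = 0.10
        curve = fpr_curve(dists)
        direct = min(c for c, f in curve.items() if f <= target)
        assert choose_threshold(dists, target) == direct

    def test_choose_threshold_degenerate_target(self):
        assert choose_threshold(self._dists(), 1.0) == 0

    def test_unreachable_target_errors(self):
        real = np.array([1, 1, 1])
        null = np.array([[5], [6], [7]])
        with pytest.raises(ValueError, match="unreachable"):
            choose_threshold(CountDistributions(real, null), 0.01)


class TestRunGeneSignificance:
    def test_counts_and_threshold_convention(self, rng):
        """Shifted genes reach the >= 7-of-20 significant-point convention
        far more often than expected by chance (per-draw power varies)."""
        cfg = SignificanceConfig(B=200, G=2, df_real="gcv")
        model = sine_model(n=20)
        counts = []
        nulls_seen = []
        for i in range(12):
            pair = make_pair(model, constant_shift(5.0), NoiseSpec(sd=0.3), rng=rng)
            res, nulls = run_gene_significance(pair, cfg, rng=np.random.default_rng(100 + i))
            assert res.n_significant == int(np.sum(res.pointwise_p < cfg.alpha))
            counts.append(res.n_significant)
            nulls_seen.append(nulls)
        at_convention = sum(c >= 7 for c in counts)
        assert at_convention >= 4  # zero-shift genes essentially never reach 7
        nulls_seen = np.concatenate(nulls_seen)
        assert np.all((nulls_seen >= 0) & (nulls_seen <= 20))

    def test_null_count_near_alpha_level(self, rng):
        """Zero-shift genes average about alpha*N significant points.

        Asserted coarsely (within 3) since neighbouring points are correlated.
        """
        cfg = SignificanceConfig(B=500, G=0, df_real="gcv")
        model = sine_model(n=20)
        counts = []
        for i in range(50):
            pair = make_pair(model, constant_shift(0.0), NoiseSpec(sd=0.3), rng=rng)
            res, _ = run_gene_significance(pair, cfg, rng=np.random.default_rng(100 + i))
            counts.append(res.n_significant)
        assert abs(np.mean(counts) - 0.05 * 20) <= 3.0

    def test_reproducible_with_fixed_seed(self, rng):
        cfg = SignificanceConfig(B=50, G=3, df_real="gcv")
        pair = make_pair(sine_model(n=20), constant_shift(3.0), NoiseSpec(sd=0.3), rng=rng)
        r1, n1 = run_gene_significance(pair, cfg, rng=np.random.default_rng(9))
        r2, n2 = run_gene_significance(pair, cfg, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(r1.pointwise_p, r2.pointwise_p)
        np.testing.assert_array_equal(n1, n2)
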