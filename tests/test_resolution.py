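"""Distance strata, CV curves, rescaled collapse and the crossover fit."""
import numpy as np
import pytest

from hicforge.resolution import (
    DistanceStratum,
    cumulative_distribution,
    cv_curve,
    cv_improvement,
    mean_variance_fit,
    rescale_collapse,
    resolution_estimate,
    stratify,
)
from hicforge.simulate import mixed_poisson_counts


def regular_positions(n, d=400):
    return np.arange(n) * d + d / 2


class TestStratify:
    def test_bruteforce_membership_oracle(self, rng):
        """Stratum membership on a regular 400-bp map vs direct pair
        enumeration (s = 1400 +/- 350 covers fragment offsets 3 and 4...)."""
        n = 60
        pos = regular_positions(n)
        M = rng.poisson(5.0, (n, n)).astype(float)
        M = (M + M.T) / 2
        s, hw, s_max = 1400.0, 350.0, 4000.0
        strata = stratify(M, pos, [s], hw, s_max)
        # oracle: enumerate all pairs independently
        expected = []
        for i in range(n):
            if pos[i] > pos.max() - (s_max + hw):
                continue
            for j in range(n):
                d = pos[j] - pos[i]
                if s - hw <= d <= s + hw:
                    expected.append(M[i, j])
        assert sorted(strata[0].counts.tolist()) == sorted(expected)
        # offsets 1200 and 1600 bp = 3 and 4 fragments
        n_left = np.sum(pos <= pos.max() - (s_max + hw))
        assert strata[0].n == 2 * n_left

    def test_constant_cardinality_across_s(self, rng):
        n = 100
        pos = regular_positions(n)
        M = rng.poisson(2.0, (n, n)).astype(float)
        M = (M + M.T) / 2
        s_vals = np.arange(1200, 8001, 400.0)
        strata = stratify(M, pos, s_vals, 150, s_max=8000)
        assert len({st.n for st in strata}) == 1

    def test_constant_matrix_zero_cv(self):
        n = 40
        M = np.full((n, n), 7.0)
        strata = stratify(M, regular_positions(n), [1200, 2000], 350, 3000)
        for st in strata:
            assert st.cv == 0.0

    def test_poisson_cv_law(self, rng):
        n = 200
        M = rng.poisson(100.0, (n, n)).astype(float)
        M = np.triu(M) + np.triu(M, 1).T
        strata = stratify(M, regular_positions(n), [2000.0], 350, 3000)
        assert strata[0].cv == pytest.approx(0.1, rel=0.15)

    def test_empty_stratum_raises(self):
        M = np.ones((10, 10))
        with pytest.raises(ValueError):
            stratify(M, regular_positions(10), [150.0], 10, 200)


class TestCumulativeDistribution:
    def test_order_statistics(self):
        st = DistanceStratum(1000, 100, np.array([0, 0, 1, 3]))
        cd = cumulative_distribution(st)
        assert cd.median == 0.5
        assert cd.blind_fraction == 0.5
        assert cd.q75 > cd.q25

    def test_degenerate_step(self):
        st = DistanceStratum(1000, 100, np.full(10, 4.0))
        cd = cumulative_distribution(st)
        assert cd.iqr == 0 and cd.median == 4.0 and cd.blind_fraction == 0.0

    def test_narrower_iqr_for_homogeneous_map(self, rng):
        """At matched depth, a homogeneous (regular-map-like) stratum has a
        strictly narrower count distribution than a heterogeneous one."""
        homogeneous = DistanceStratum(0, 0, mixed_poisson_counts(20, 0.1, 4000, rng))
        heterogeneous = DistanceStratum(0, 0, mixed_poisson_counts(20, 1.0, 4000, rng))
        assert (
            cumulative_distribution(homogeneous).iqr
            < cumulative_distribution(heterogeneous).iqr
        )


class TestCvCurve:
    def test_poisson_limit(self, rng):
        n = 150
        for mu in (25.0, 100.0):
            M = rng.poisson(mu, (n, n)).astype(float)
            M = np.triu(M) + np.triu(M, 1).T
            tab = cv_curve(M, regular_positions(n), [1600, 2400, 4000], 350,
                           s_max=5000)
            assert np.allclose(tab.cv, 1 / np.sqrt(mu), rtol=0.2)

    def test_cv_halves_with_quadrupled_depth(self, rng):
        n = 150
        M1 = rng.poisson(10.0, (n, n)).astype(float)
        M4 = rng.poisson(40.0, (n, n)).astype(float)
        M1 = np.triu(M1) + np.triu(M1, 1).T
        M4 = np.triu(M4) + np.triu(M4, 1).T
        pos = regular_positions(n)
        cv1 = cv_curve(M1, pos, [2000.0], 350, 3000).cv[0]
        cv4 = cv_curve(M4, pos, [2000.0], 350, 3000).cv[0]
        assert cv4 == pytest.approx(cv1 / 2, rel=0.2)


class TestCvImprovement:
    def test_null_target_inside_bulk(self, rng):
        cvs = [1 + 0.05 * rng.standard_normal(20) for _ in range(8)]
        res = cv_improvement(cvs[0], cvs[1:])
        assert 0.0 < res.rank < 1.0

    def test_improved_target_in_left_tail(self, rng):
        controls = [1 + 0.05 * rng.standard_normal(20) for _ in range(7)]
        target = 0.5 * (1 + 0.05 * rng.standard_normal(20))
        res = cv_improvement(target, controls)
        assert res.target_mean < 0
        assert res.rank == 0.0 and res.significant

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cv_improvement(np.ones(5), [np.ones(6)])


class TestRescaleCollapse:
    def test_gaussian_regime_collapses(self, rng):
        strata = [
            DistanceStratum(s, 1, mixed_poisson_counts(mu, 0.5, 5000, rng))
            for s, mu in enumerate([200.0, 400.0, 800.0])
        ]
        res = rescale_collapse(strata)
        assert res.statistic < 0.1

    def test_poisson_regime_does_not_collapse(self, rng):
        strata = [
            DistanceStratum(s, 1, mixed_poisson_counts(mu, 0.0, 5000, rng))
            for s, mu in enumerate([0.5, 2.0, 8.0])
        ]
        res = rescale_collapse(strata)
        assert res.statistic > 0.3

    def test_identical_strata_statistic_zero(self):
        counts = np.arange(100.0)
        strata = [DistanceStratum(s, 1, counts.copy()) for s in (1, 2)]
        assert rescale_collapse(strata).statistic == 0.0


class TestMeanVarianceFit:
    @pytest.mark.parametrize("c_true", [0.1, 0.316, 0.5, 1.0])
    def test_recovers_latent_cv(self, c_true):
        rng = np.random.default_rng(42)
        strata = [
            DistanceStratum(k, 0.5, mixed_poisson_counts(mu, c_true, 5000, rng))
            for k, mu in enumerate(np.geomspace(0.1, 100, 30))
        ]
        fit = mean_variance_fit(strata)
        assert fit.c == pytest.approx(c_true, rel=0.1)
        assert fit.mu_star * fit.c**2 == pytest.approx(1.0)  # exact identity
        assert fit.significant

    def test_pure_poisson_sentinel(self, rng):
        strata = [
            DistanceStratum(k, 0.5, mixed_poisson_counts(mu, 0.0, 3000, rng))
            for k, mu in enumerate(np.geomspace(0.5, 20, 12))
        ]
        fit = mean_variance_fit(strata)
        assert not fit.significant
        assert fit.c < 0.15
        assert "Poisson" in fit.summary() or np.isfinite(fit.mu_star)

    def test_variance_law_predicted(self, rng):
        strata = [
            DistanceStratum(k, 0.5, mixed_poisson_counts(mu, 0.5, 8000, rng))
            for k, mu in enumerate(np.geomspace(1, 50, 10))
        ]
        fit = mean_variance_fit(strata)
        mu = fit.points["mu"].to_numpy()
        assert np.allclose(fit.predicted_var(mu), mu + fit.c**2 * mu**2)


class TestResolutionEstimate:
    def _events(self, R, seed, L=120_000):
        from hicforge import simulate

        cfg = simulate.preset("g1", L=L, seed=seed, c=0.5)
        rng = np.random.default_rng(seed)
        fm = simulate.make_restriction_map(cfg, seed=rng)
        model = simulate.build_contact_model(fm, cfg, seed=rng)
        return simulate.sample_reads(model, R, seed=rng), cfg

    def test_matches_bruteforce_scan(self):
        from hicforge.resolution import CrossoverFit, mean_count_at
        import pandas as pd

        events, cfg = self._events(150_000, seed=6)
        fit = CrossoverFit(c=0.5, c_se=0.01, points=pd.DataFrame(),
                           residuals=np.empty(0))
        grid = [400, 800, 1600, 3200, 6400]
        b = resolution_estimate(events, cfg.chrom, cfg.L, 8000.0, fit, grid)
        oracle = None
        for cand in grid:
            m = mean_count_at(events, cfg.chrom, cfg.L, 8000.0, cand)
            if m is not None and m >= fit.mu_star:
                oracle = cand
                break
        assert b == oracle is not None

    def test_monotone_in_depth(self):
        from hicforge.resolution import CrossoverFit
        import pandas as pd

        fit = CrossoverFit(c=0.5, c_se=0.01, points=pd.DataFrame(),
                           residuals=np.empty(0))
        grid = [400, 800, 1600, 3200, 6400, 12800]
        shallow, cfg = self._events(50_000, seed=7)
        deep, _ = self._events(200_000, seed=7)
        b_lo = resolution_estimate(shallow, cfg.chrom, cfg.L, 10_000.0, fit, grid)
        b_hi = resolution_estimate(deep, cfg.chrom, cfg.L, 10_000.0, fit, grid)
        assert b_hi is not None and (b_lo is None or b_hi <= b_lo)

    def test_fragment_scale_boundary(self):
        """mu* = 1 already reached at the fragment scale: the resolution is
        one fragment."""
        from hicforge.resolution import CrossoverFit
        import pandas as pd

        events, cfg = self._events(400_000, seed=8)
        fit = CrossoverFit(c=1.0, c_se=0.01, points=pd.DataFrame(),
                           residuals=np.empty(0))
        b = resolution_estimate(events, cfg.chrom, cfg.L, 3000.0, fit,
                                [400, 800, 1600])
        assert b == 400

    def test_unresolved_reported_as_none(self):
        from hicforge.resolution import CrossoverFit
        import pandas as pd

        events, cfg = self._events(2_000, seed=9)
        fit = CrossoverFit(c=0.05, c_se=0.001, points=pd.DataFrame(),
                           residuals=np.empty(0))
        assert resolution_estimate(events, cfg.chrom, cfg.L, 10_000.0, fit,
                                   [400, 800]) is None
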