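"""First-level beta regression and least-squares-means contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from dyadsync.first_level import (
    DesignSpec,
    beta_regression_fit,
    compress_boundary,
    lsmeans_contrast,
    pool_units,
    run_first_level,
)


def simulate_beta(rng, eta, phi=30.0):
    """Beta responses with logit-link mean eta (array) and precision phi."""
    mu = special.expit(eta)
    return rng.beta(mu * phi, (1 - mu) * phi)


class TestDesignSpec:
    def test_valid(self):
        DesignSpec("fb", "fb2_minus_fb1")
        DesignSpec("fb_pe", "pe_fb3_minus_fb2")

    def test_mismatched_contrast_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec("fb", "pe_fb2")
        with pytest.raises(ValueError):
            DesignSpec("nope", "fb2_minus_fb1")


class TestCompression:
    def test_boundaries_moved_inside(self):
        y = np.array([0.0, 0.5, 1.0])
        z = compress_boundary(y)
        assert z.min() > 0 and z.max() < 1

    def test_interior_barely_changed(self, rng):
        y = rng.uniform(0.2, 0.8, 400)
        z = compress_boundary(y)
        assert np.abs(z - y).max() < 0.5 / 400 + 1e-12


class TestBetaRegression:
    def test_parameter_recovery_coverage(self, rng):
        """ML recovers logit(mu)=0.5 within 3 SE in >= 95% of replicates."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = simulate_beta(rng, np.full(500, 0.5))
            coef, cov = beta_regression_fit(y, np.ones((500, 1)))
            se = np.sqrt(cov[0, 0])
            hits += abs(coef[0] - 0.5) < 3 * se
        assert hits / n_rep >= 0.95

    def test_null_group_contrast_calibrated(self, rng):
        """Two identical groups: |t| < 2 in roughly 95% of null reps."""
        n_rep, n = 200, 300
        X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        n_small = 0
        for _ in range(n_rep):
            y = simulate_beta(rng, np.zeros(n))
            coef, cov = beta_regression_fit(y, X)
            t = coef[1] / np.sqrt(cov[1, 1])
            n_small += abs(t) < 2
        assert 0.90 <= n_small / n_rep <= 0.99

    def test_matches_independent_ml_oracle(self, rng):
        """Coefficients agree with an independently coded beta likelihood
        maximized by a generic optimizer on a small fixture."""
        n = 30
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        y = compress_boundary(simulate_beta(rng, 0.3 + 0.5 * X[:, 1]))
        coef, _ = beta_regression_fit(y, X)

        def nll(theta):
            mu = special.expit(X @ theta[:2])
            phi = np.exp(theta[2])
            return -stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()

        res = optimize.minimize(nll, [0.0, 0.0, 2.0], method="Nelder-Mead",
                                options=dict(xatol=1e-8, fatol=1e-10,
                                             maxiter=5000))
        assert np.allclose(coef, res.x[:2], atol=1e-2)

    def test_boundary_values_rejected(self, rng):
        y = rng.uniform(0.2, 0.8, 50)
        y[0] = 1.0
        with pytest.raises(ValueError, match="strictly"):
            beta_regression_fit(y, np.ones((50, 1)))

    def test_rank_deficient_rejected(self, rng):
        y = compress_boundary(rng.uniform(0.2, 0.8, 50))
        X = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="rank"):
            beta_regression_fit(y, X)


class TestLsmeans:
    def test_identical_groups_zero(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        y = simulate_beta(rng, np.zeros(n), phi=80)
        coef, cov = beta_regression_fit(y, X)
        est, se = lsmeans_contrast(coef, cov, np.array([0.0, 1.0]))
        assert abs(est) < 3 * se

    def test_balanced_design_matches_group_means(self, rng):
        """Treatment contrast ~ difference of logit group means."""
        n = 4000
        g = np.repeat([0, 1], n // 2)
        X = np.column_stack([np.ones(n), g]).astype(float)
        y = simulate_beta(rng, 0.2 + 0.6 * g, phi=60)
        coef, cov = beta_regression_fit(y, X)
        est, _ = lsmeans_contrast(coef, cov, np.array([0.0, 1.0]))
        oracle = special.logit(y[g == 1].mean()) - special.logit(
            y[g == 0].mean()
        )
        assert est == pytest.approx(oracle, abs=0.05)

    def test_se_matches_bootstrap(self, rng):
        """Delta-method SE agrees with a nonparametric bootstrap."""
        n = 240
        g = np.repeat([0, 1], n // 2)
        X = np.column_stack([np.ones(n), g]).astype(float)
        y = compress_boundary(simulate_beta(rng, 0.1 + 0.4 * g, phi=25))
        coef, cov = beta_regression_fit(y, X)
        _, se = lsmeans_contrast(coef, cov, np.array([0.0, 1.0]))
        boot = []
        for _ in range(1000):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(g == 0), n // 2),
                rng.choice(np.flatnonzero(g == 1), n // 2),
            ])
            c, _ = beta_regression_fit(y[idx], X[idx])
            boot.append(c[1])
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.15)

    def test_inestimable_contrast_rejected(self, rng):
        y = compress_boundary(rng.uniform(0.2, 0.8, 60))
        coef, cov = beta_regression_fit(y, np.ones((60, 1)))
        with pytest.raises(ValueError):
            lsmeans_contrast(coef, cov, np.array([1.0, 1.0]))


def make_conn_table(rng, n_pairs=6, n_units=2, n_trials=40, planted_pair=0,
                    shift=0.8):
    """Connectivity-table fixture: beta ISPC with a logit-scale FB2 shift
    planted on one pair."""
    rows = []
    pairs = [(f"c{i}", f"c{j}") for i in range(4) for j in range(i + 1, 4)]
    pairs = pairs[:n_pairs]
    for u in range(n_units):
        for (ci, cj) in pairs:
            planted = (ci, cj) == pairs[planted_pair]
            for t in range(n_trials):
                for rep in (1, 2, 3):
                    eta = -0.5 + (shift if planted and rep == 2 else 0.0)
                    rows.append(
                        dict(unit=f"u{u}", trial=t, rep=rep, chan_i=ci,
                             chan_j=cj, pair=f"{ci}-{cj}", band="alpha",
                             window="early",
                             ispc=float(simulate_beta(rng, np.array([eta]),
                                                      phi=25)[0]))
                    )
    return pd.DataFrame(rows)


class TestRunFirstLevel:
    def test_planted_pair_detected_and_pooled(self, rng):
        table = make_conn_table(rng)
        out = run_first_level(table, DesignSpec("fb", "fb2_minus_fb1"))
        assert len(out) == 6
        assert (out["n_units"] == 2).all()
        best = out.loc[out["estimate"].idxmax()]
        assert best["connection"] == "c0-c1"
        assert best["estimate"] > 2 * best["se"]

    def test_pooling_none_gives_unit_rows(self, rng):
        table = make_conn_table(rng, n_pairs=2)
        out = run_first_level(table, DesignSpec("fb", "fb2_minus_fb1"),
                              pooling="none")
        assert len(out) == 4  # 2 pairs x 2 units
        assert "unit" in out.columns

    def test_inverse_variance_pooling_math(self):
        est, se = pool_units([(1.0, 0.1), (0.0, 0.1)])
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.1 / np.sqrt(2))
        est, se = pool_units([(1.0, 0.1), (0.0, 1e3)])
        assert est == pytest.approx(1.0, abs=1e-4)

    def test_fb_adj_interaction_detected(self, rng):
        """Planted low-low-specific FB3 increase shows in the adjustment
        interaction contrast."""
        rows = []
        labels = []
        for u in range(2):
            for t in range(60):
                lab = "low_low" if t % 2 == 0 else "high_high"
                labels.append(dict(unit=f"u{u}", trial=t, label=lab))
                for rep in (1, 2, 3):
                    eta = -0.4
                    if lab == "low_low" and rep == 3:
                        eta += 0.8
                    rows.append(
                        dict(unit=f"u{u}", trial=t, rep=rep, chan_i="a",
                             chan_j="b", pair="a-b", band="alpha",
                             window="early",
                             ispc=float(simulate_beta(rng, np.array([eta]),
                                                      phi=25)[0]))
                    )
        out = run_first_level(
            pd.DataFrame(rows),
            DesignSpec("fb_adj", "adj_low_minus_high_fb3_minus_fb2"),
            labels=pd.DataFrame(labels),
        )
        assert len(out) == 1
        assert out["estimate"].iloc[0] > 2 * out["se"].iloc[0]

    def test_fb_pe_slope_detected(self, rng):
        """Planted PE-ISPC coupling at FB3 yields a positive PE slope."""
        rows, pes = [], []
        for u in range(2):
            for t in range(80):
                pe = float(rng.normal())
                for rep in (2, 3):
                    pes.append(dict(unit=f"u{u}", trial=t, rep=rep, pe=pe))
                for rep in (1, 2, 3):
                    eta = -0.4 + (0.5 * pe if rep == 3 else 0.0)
                    rows.append(
                        dict(unit=f"u{u}", trial=t, rep=rep, chan_i="a",
                             chan_j="b", pair="a-b", band="alpha",
                             window="early",
                             ispc=float(simulate_beta(rng, np.array([eta]),
                                                      phi=25)[0]))
                    )
        out = run_first_level(
            pd.DataFrame(rows), DesignSpec("fb_pe", "pe_fb3"),
            pe=pd.DataFrame(pes),
        )
        assert out["estimate"].iloc[0] > 2 * out["se"].iloc[0]
        out2 = run_first_level(
            pd.DataFrame(rows), DesignSpec("fb_pe", "pe_fb3_minus_fb2"),
            pe=pd.DataFrame(pes),
        )
        assert out2["estimate"].iloc[0] > 0

    def test_mixed_band_table_rejected(self, rng):
        table = make_conn_table(rng, n_pairs=1, n_units=1, n_trials=5)
        other = table.copy()
        other["band"] = "beta"
        with pytest.raises(ValueError, match="band"):
            run_first_level(pd.concat([table, other]),
                            DesignSpec("fb", "fb2_minus_fb1"))

    def test_missing_pe_table_rejected(self, rng):
        table = make_conn_table(rng, n_pairs=1, n_units=1, n_trials=5)
        with pytest.raises(ValueError, match="PE"):
            run_first_level(table, DesignSpec("fb_pe", "pe_fb2"))
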