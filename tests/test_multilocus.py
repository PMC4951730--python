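"""Empirical-Bayes multi-locus model, screening, declaration and the pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from gcim import (
    SimulationConfig,
    eb_fit,
    fill_expected,
    gcim_full,
    insert_pseudo_markers,
    lrt_declare,
    screen_candidates,
    simulate,
)
from gcim.multilocus import LOD_TO_LRT, MultiLocusFit, _merge_reports


def _direct_map_gamma(y, X, Z, seed=0, n_starts=8):
    """Independent maximizer of the penalized marginal posterior.

    Optimizes the observed-data log-likelihood plus the -log sigma_k^2
    penalty over log prior variances (bounded below) with multi-start
    L-BFGS, then returns the posterior-mean effects at the optimum. The
    improper prior makes the objective diverge as any variance reaches
    zero, so the box corner would dominate for an arbitrarily low bound;
    the lower bound stays at 1e-4 x var(y), far from that singularity but
    small enough that a bounded null component still contributes a
    negligible effect. Starts include unit variances and marginal
    least-squares magnitudes alongside random points.
    """
    n, K = Z.shape
    lo = np.log(1e-4 * float(np.var(y)))

    def neg(theta):
        s2k = np.exp(theta[:K])
        s2 = np.exp(theta[K])
        V = Z @ (s2k[:, None] * Z.T) + s2 * np.eye(n)
        _, ld = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        a = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ a
        return 0.5 * (n * np.log(2 * np.pi) + ld + r @ Vi @ r) + np.sum(theta[:K])

    rng = np.random.default_rng(seed)
    lsq = np.maximum((Z.T @ (y - y.mean()) / np.maximum((Z**2).sum(0), 1)) ** 2, 1e-4)
    starts = [
        np.concatenate([np.zeros(K), [np.log(np.var(y))]]),
        np.concatenate([np.log(lsq), [np.log(np.var(y))]]),
    ]
    for _ in range(n_starts):
        starts.append(
            np.concatenate(
                [rng.uniform(np.log(1e-4), np.log(4.0), K), [np.log(np.var(y))]]
            )
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg, np.maximum(x0, lo), method="L-BFGS-B",
            bounds=[(lo, np.log(1e4))] * K + [(np.log(1e-6), np.log(1e4))],
        )
        if best is None or res.fun < best.fun:
            best = res
    s2k = np.exp(best.x[:K])
    s2 = np.exp(best.x[K])
    V = Z @ (s2k[:, None] * Z.T) + s2 * np.eye(n)
    Vi = np.linalg.inv(V)
    a = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return s2k * (Z.T @ Vi @ (y - X @ a))


class TestEbFit:
    def test_shrinks_below_ols_on_noise(self):
        rng = np.random.default_rng(0)
        n, K = 200, 10
        X = np.ones((n, 1))
        Z = rng.choice([-1.0, 1.0], size=(n, K))
        y = rng.standard_normal(n)
        fit = eb_fit(y, X, Z)
        coef, *_ = np.linalg.lstsq(np.hstack([X, Z]), y, rcond=None)
        ols = coef[1:]
        assert np.all(np.abs(fit.gamma) <= np.abs(ols) + 1e-12)

    def test_recovers_single_true_effect(self):
        rng = np.random.default_rng(1)
        n, K = 400, 10
        hits = 0
        reps = 20
        for _ in range(reps):
            X = np.ones((n, 1))
            Z = rng.choice([-1.0, 1.0], size=(n, K))
            gamma = np.zeros(K)
            gamma[0] = 2.0
            y = 5.0 + Z @ gamma + rng.standard_normal(n)
            fit = eb_fit(y, X, Z)
            nulls = np.abs(fit.gamma[1:])
            ok = np.sign(fit.gamma[0]) > 0 and abs(fit.gamma[0]) > 5 * max(
                np.median(nulls), 1e-12
            )
            hits += ok
        assert hits >= 0.9 * reps

    def test_no_shrinkage_limit_matches_ols(self):
        # a very strong effect against tiny noise: the prior variance blows
        # up and the posterior mean approaches the least-squares estimate
        rng = np.random.default_rng(2)
        n = 100
        X = np.ones((n, 1))
        z = rng.choice([-1.0, 1.0], n)
        y = 3.0 + 5.0 * z + rng.normal(0.0, 0.05, n)
        fit = eb_fit(y, X, z.reshape(-1, 1))
        coef, *_ = np.linalg.lstsq(np.column_stack([X, z]), y, rcond=None)
        assert fit.gamma[0] == pytest.approx(coef[1], abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_posterior_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        n, K = 25, 4
        X = np.ones((n, 1))
        Z = rng.choice([-1.0, 1.0], size=(n, K))
        y = 5.0 + 2.0 * Z[:, 0] + rng.standard_normal(n) * 0.8
        fit = eb_fit(y, X, Z)
        g_ref = _direct_map_gamma(y, X, Z, seed=seed)
        rel = np.linalg.norm(fit.gamma - g_ref) / max(np.linalg.norm(g_ref), 1e-9)
        assert rel < 1e-2

    def test_em_monotone_within_active_set(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            n, K = 60, 8
            X = np.ones((n, 1))
            Z = rng.choice([-1.0, 1.0], size=(n, K))
            y = 1.0 + 1.5 * Z[:, 2] + rng.standard_normal(n)
            fit = eb_fit(y, X, Z)
            tr, act = fit.loglik_trace, fit.active_trace
            for i in range(1, len(tr)):
                if act[i] == act[i - 1]:
                    assert tr[i] >= tr[i - 1] - 1e-8 * max(1.0, abs(tr[i - 1]))

    def test_candidate_cap(self):
        n = 10
        Z = np.random.default_rng(4).choice([-1.0, 1.0], size=(n, 2 * n + 1))
        with pytest.raises(ValueError, match="cap"):
            eb_fit(np.zeros(n), np.ones((n, 1)), Z)

    def test_duplicate_columns_warn_but_fit(self):
        rng = np.random.default_rng(5)
        n = 50
        z = rng.choice([-1.0, 1.0], n)
        Z = np.column_stack([z, z])
        y = 1.0 + z + rng.standard_normal(n)
        with pytest.warns(UserWarning, match="duplicate"):
            fit = eb_fit(y, np.ones((n, 1)), Z)
        assert np.all(np.isfinite(fit.gamma))


class TestScreenCandidates:
    def _fit(self, gamma, post_var, s2k):
        K = len(gamma)
        return MultiLocusFit(
            gamma=np.asarray(gamma, float),
            sigma_k2=np.asarray(s2k, float),
            posterior_var=np.asarray(post_var, float),
            alpha=np.zeros(1),
            sigma2=1.0,
            iterations=1,
            converged=True,
            loglik_trace=np.zeros(1),
            active_trace=np.ones(1, dtype=int),
        )

    def test_collapsed_priors_give_empty_set(self):
        fit = self._fit([0.5, -0.2], [0.0, 0.0], [0.0, 0.0])
        kept, pvals = screen_candidates(fit, n=100)
        assert kept.size == 0
        assert np.all(pvals == 1.0)

    def test_boundary_statistic_excluded(self, monkeypatch):
        # exact equality with the F quantile must be excluded (strict <)
        import gcim.multilocus as ml

        monkeypatch.setattr(ml.stats.f, "isf", lambda *a, **k: 4.0)
        fit = self._fit([2.0], [1.0], [1.0])  # statistic exactly 4.0
        kept, _ = screen_candidates(fit, n=100, alpha=0.01)
        assert kept.size == 0

    def test_statistic_above_quantile_kept(self, monkeypatch):
        import gcim.multilocus as ml

        monkeypatch.setattr(ml.stats.f, "isf", lambda *a, **k: 4.0)
        fit = self._fit([2.0000001], [1.0], [1.0])
        kept, _ = screen_candidates(fit, n=100, alpha=0.01)
        assert kept.size == 1

    def test_strong_effect_retained(self):
        n = 100
        fit = self._fit([2.0], [0.05], [1.0])
        kept, _ = screen_candidates(fit, n=n)
        assert list(kept) == [0]


class TestLrtDeclare:
    def test_empty_kept_set(self):
        report = lrt_declare(np.zeros(10), np.ones((10, 1)), None)
        assert len(report) == 0

    def test_lod_matches_independent_recomputation(self):
        rng = np.random.default_rng(6)
        n = 120
        X = np.ones((n, 1))
        Z = rng.choice([-1.0, 1.0], size=(n, 3))
        y = 2.0 + 1.2 * Z[:, 0] + 0.5 * Z[:, 1] + rng.standard_normal(n)
        report = lrt_declare(y, X, Z, method="refit", lod_threshold=0.0)
        # recompute the drop-one LRT by explicit least squares
        def rss(cols):
            A = np.column_stack([X] + [Z[:, j] for j in cols])
            c, *_ = np.linalg.lstsq(A, y, rcond=None)
            r = y - A @ c
            return float(r @ r)

        full = rss([0, 1, 2])
        for row, k in zip(report.itertuples(), range(3)):
            want = n * np.log(rss([j for j in range(3) if j != k]) / full)
            assert row.lod == pytest.approx(want / LOD_TO_LRT, rel=1e-10)
        # declaration threshold: only LOD >= 2.5 rows survive the default
        declared = lrt_declare(y, X, Z, method="refit")
        assert np.all(declared["lod"] >= 2.5)

    def test_plugin_lrt_shrinks_with_effects(self):
        rng = np.random.default_rng(7)
        n = 200
        X = np.ones((n, 1))
        z = rng.choice([-1.0, 1.0], n)
        y = 1.0 + 0.6 * z + rng.standard_normal(n)
        coef, *_ = np.linalg.lstsq(np.column_stack([X, z]), y, rcond=None)
        full = lrt_declare(y, X, z.reshape(-1, 1), effects=[coef[1]],
                           method="plugin", lod_threshold=0.0)
        half = lrt_declare(y, X, z.reshape(-1, 1), effects=[0.5 * coef[1]],
                           method="plugin", lod_threshold=0.0)
        assert half["lod"].iloc[0] < full["lod"].iloc[0]

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        n = 150
        X = np.ones((n, 1))
        Z = rng.choice([-1.0, 1.0], size=(n, 4))
        y = Z @ [1.0, 0.8, 0.0, 0.6] + rng.standard_normal(n)
        info = pd.DataFrame(
            {
                "chromosome": ["1"] * 4,
                "position_cM": [10.0, 20.0, 30.0, 40.0],
                "name": list("abcd"),
                "marker_interval": [""] * 4,
            }
        )
        r1 = lrt_declare(y, X, Z, info=info, method="refit")
        perm = [2, 0, 3, 1]
        r2 = lrt_declare(y, X, Z[:, perm], info=info.iloc[perm], method="refit")
        assert sorted(r1["name"]) == sorted(r2["name"])
        m1 = r1.set_index("name")["lod"]
        m2 = r2.set_index("name")["lod"]
        for nm in m1.index:
            assert m1[nm] == pytest.approx(m2[nm], rel=1e-10)

    def test_collinear_columns_warn(self):
        rng = np.random.default_rng(9)
        n = 50
        z = rng.choice([-1.0, 1.0], n)
        y = z + rng.standard_normal(n)
        with pytest.warns(UserWarning, match="collinear"):
            lrt_declare(y, np.ones((n, 1)), np.column_stack([z, z]),
                        method="refit", lod_threshold=0.0)


class TestMergeReports:
    def _rep(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "chromosome", "position_cM", "name", "marker_interval",
                "effect", "lod", "p_value", "r2_percent",
            ],
        )

    def test_dedup_keeps_higher_lod(self):
        r1 = self._rep([["1", 100.0, "a", "", 1.0, 3.0, 1e-4, 5.0]])
        r2 = self._rep([["1", 100.5, "b", "", 1.1, 4.0, 1e-5, 6.0]])
        merged = _merge_reports(r1, r2, window=1.0)
        assert len(merged) == 1
        assert merged["name"].iloc[0] == "b"

    def test_distant_declarations_kept(self):
        r1 = self._rep([["1", 100.0, "a", "", 1.0, 3.0, 1e-4, 5.0]])
        r2 = self._rep([["1", 150.0, "b", "", 1.1, 4.0, 1e-5, 6.0]])
        assert len(_merge_reports(r1, r2, window=1.0)) == 2


class TestGcimFull:
    def test_deterministic(self, single_qtl_run):
        data, grid, filled = single_qtl_run
        r1 = gcim_full(data.y, filled, grid)
        r2 = gcim_full(data.y, filled, grid)
        pd.testing.assert_frame_equal(r1.report, r2.report)

    def test_single_qtl_declared_near_truth(self, single_qtl_run):
        data, grid, filled = single_qtl_run
        res = gcim_full(data.y, filled, grid)
        pos = res.report["position_cM"].to_numpy()
        assert np.any(np.abs(pos - 1000.0) <= 5.0)
        assert np.all(res.report["lod"] >= 2.5)
        assert np.all((res.report["r2_percent"] >= 0) & (res.report["r2_percent"] <= 100))

    def test_null_input_near_empty(self):
        d = simulate(SimulationConfig(n=400, qtl=(), seed=2))
        grid = insert_pseudo_markers(d.gmap, 1.0)
        filled = fill_expected(d.geno, grid)
        res = gcim_full(d.y, filled, grid)
        assert len(res.report) <= 2
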