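"""GRM, mixed-model null fits, score tests, BH-FDR and thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from paddygwas import (
    AssociationResult,
    KinshipMatrix,
    adjust_fdr,
    association_scan,
    compute_grm,
    conditional_scan,
    fdr_threshold,
    fit_null_model,
    run_gwas,
)
from .conftest import make_matrix


def brute_force_bh(p):
    """O(m^2) step-up rule: q_i = min over tails of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        tail = [m * p[order[r - 1]] / r for r in range(rank, m + 1)]
        q[idx] = min(1.0, min(tail))
    return q


def logistic_null_score_p(y, g):
    """From-scratch intercept-only logistic fit + score test for one marker."""
    n = len(y)
    b = 0.0
    for _ in range(200):
        mu = 1 / (1 + np.exp(-b))
        step = np.sum(y - mu) / (n * mu * (1 - mu))
        b += step
        if abs(step) < 1e-13:
            break
    mu = np.full(n, 1 / (1 + np.exp(-b)))
    w = mu * (1 - mu)
    U = g @ (y - mu)
    V = g @ (w * g) - (g @ w) ** 2 / w.sum()
    return chi2.sf(U * U / V, df=1)


class TestGRM:
    def test_hand_computed_3x2(self):
        # dosages: acc x 2 markers; p = (mean/2) per marker
        X = np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
        G = make_matrix(X)
        K = compute_grm(G).values
        p = X.mean(axis=0) / 2
        Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = Z @ Z.T / 2
        assert np.allclose(K, expected, atol=1e-12)

    def test_duplicate_accessions(self):
        X = np.array([[0.0, 2.0, 0.0], [0.0, 2.0, 0.0], [2.0, 0.0, 2.0]])
        K = compute_grm(make_matrix(X)).values
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(6, 12)) * 2.0
        K1 = compute_grm(make_matrix(X)).values
        perm = rng.permutation(6)
        K2 = compute_grm(make_matrix(X[perm])).values
        assert np.allclose(K2, K1[np.ix_(perm, perm)], atol=1e-12)

    def test_monomorphic_markers_skipped_or_rejected(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
        K = compute_grm(make_matrix(X)).values  # second marker skipped
        assert K.shape == (3, 3)
        with pytest.raises(ValueError):
            compute_grm(make_matrix(np.zeros((3, 2))))

    def test_psd_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, m = rng.integers(3, 15), rng.integers(2, 25)
            X = rng.integers(0, 2, size=(n, m)) * 2.0
            X[rng.random((n, m)) < 0.1] = np.nan
            poly = np.nanvar(X, axis=0) > 0
            if not poly.any():
                continue
            K = compute_grm(make_matrix(X)).values
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestNullModel:
    def test_identity_kinship_reml_matches_grid_search(self):
        rng = np.random.default_rng(1)
        n = 40
        y = rng.standard_normal(n)
        K = KinshipMatrix(np.eye(n), [f"A{i}" for i in range(n)])
        fit = fit_null_model(y, None, K, response="quantitative")
        # with K = I the total variance tau + sigma2 is identified and must
        # equal the REML optimum found by brute-force grid search
        X = np.ones((n, 1))
        best = None
        for total in np.linspace(0.2, 3.0, 561):
            V = total * np.eye(n)
            Vinv = np.linalg.inv(V)
            _, ld = np.linalg.slogdet(V)
            b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            r = y - X @ b
            ll = -0.5 * (ld + np.linalg.slogdet(X.T @ Vinv @ X)[1] + r @ Vinv @ r)
            if best is None or ll > best[0]:
                best = (ll, total)
        assert fit.tau + fit.sigma2 == pytest.approx(best[1], rel=1e-2)

    def test_binary_intercept_matches_logit_mean(self):
        rng = np.random.default_rng(2)
        n = 200
        y = (rng.random(n) < 0.3).astype(float)
        K = KinshipMatrix(np.eye(n), [f"A{i}" for i in range(n)])
        fit = fit_null_model(y, None, K, response="binary", fix_tau=0.0)
        expected = np.log(y.mean() / (1 - y.mean()))
        assert fit.beta[0] == pytest.approx(expected, abs=1e-4)

    def test_collinear_covariate_dropped(self):
        rng = np.random.default_rng(3)
        n = 30
        y = rng.standard_normal(n)
        K = KinshipMatrix(np.eye(n), [f"A{i}" for i in range(n)])
        cov = np.ones((n, 1))  # duplicates the intercept
        fit = fit_null_model(y, cov, K, response="quantitative")
        assert fit.dropped_columns == [1]
        assert fit.X.shape[1] == 1

    def test_constant_phenotype_rejected(self):
        K = KinshipMatrix(np.eye(4), list("ABCD"))
        with pytest.raises(ValueError):
            fit_null_model(np.ones(4), None, K, response="binary")


class TestAssociationScan:
    def test_binary_tau_zero_equals_logistic_score_test(self):
        rng = np.random.default_rng(4)
        n, m = 50, 20
        X = rng.integers(0, 2, size=(n, m)) * 2.0
        y = (rng.random(n) < 0.4).astype(float)
        G = make_matrix(X)
        K = compute_grm(G)
        null = fit_null_model(y, None, K, response="binary", fix_tau=0.0)
        res = association_scan(G, null)
        oracle = np.array([logistic_null_score_p(y, X[:, j]) for j in range(m)])
        assert np.allclose(res.table["p"].to_numpy(), oracle, atol=1e-10)

    def test_quantitative_identity_kinship_matches_ols(self):
        # tau pinned at 0 with K = I: score test == OLS score test, which
        # agrees with the regression t-test p to 3+ decimals at n = 500
        rng = np.random.default_rng(5)
        n, m = 500, 30
        X = rng.integers(0, 2, size=(n, m)) * 2.0
        y = rng.standard_normal(n)
        G = make_matrix(X)
        K = KinshipMatrix(np.eye(n), G.accession_ids)
        null = fit_null_model(y, None, K, response="quantitative", fix_tau=0.0)
        res = association_scan(G, null)
        import statsmodels.api as sm

        for j in range(m):
            ols = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            assert res.table["p"].iloc[j] == pytest.approx(ols.pvalues[1], abs=1e-3)

    def test_affine_recoding_invariance(self):
        rng = np.random.default_rng(6)
        n, m = 60, 15
        X = rng.integers(0, 2, size=(n, m)) * 2.0
        y = (rng.random(n) < 0.5).astype(float)
        G02 = make_matrix(X)
        G01 = make_matrix(X / 2.0)
        K = compute_grm(G02)
        null = fit_null_model(y, None, K, response="binary")
        p1 = association_scan(G02, null).table["p"].to_numpy()
        p2 = association_scan(G01, null).table["p"].to_numpy()
        assert np.allclose(p1, p2, rtol=1e-10)

    def test_zero_variance_marker_flagged(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(30, 3)) * 2.0
        X[:, 1] = 0.0
        y = (rng.random(30) < 0.5).astype(float)
        G = make_matrix(X)
        null = fit_null_model(y, None, compute_grm(G), response="binary")
        res = association_scan(G, null)
        assert np.isnan(res.table["p"].iloc[1])
        assert res.table["p"].drop(index=1).notna().all()


class TestConditionalScan:
    def one_locus_panel(self):
        from paddygwas import SyntheticConfig, simulate_genotypes, simulate_phenotype

        cfg = SyntheticConfig(
            n_accessions=200,
            n_chromosomes=2,
            chrom_length_bp=8_000_000,
            n_markers_per_chrom=500,
            major_locus=(1, 4_000_000),
            modifier_loci=((2, 2_000_000), (2, 6_000_000)),
            modifier_alt_freq=0.05,  # modifiers effectively silent
            penetrance_major=1.0,
            leak_rate=0.05,  # genotype-independent phenotype noise
            switch_rate=2e-6,
            missing_rate=0.0,
            het_injection_rate=0.0,
            seed=31,
        )
        G = simulate_genotypes(cfg)
        ph = simulate_phenotype(G, cfg)
        return cfg, G, ph

    def test_conditioning_on_causal_removes_signal(self):
        cfg, G, ph = self.one_locus_panel()
        base = run_gwas(G, ph, response="binary")
        t = base.table
        near = t[(t["chrom"].astype(str) == "1") & (abs(t["pos"] - 4_000_000) < 500_000)]
        assert near["minus_log10_p"].max() >= base.sug_line
        cond = conditional_scan(G, ph, [cfg.major_locus], response="quantitative")
        tc = cond.table
        nearc = tc[(tc["chrom"].astype(str) == "1") & (abs(tc["pos"] - 4_000_000) < 500_000)]
        assert nearc["minus_log10_p"].max() < cond.sug_line

    def test_conditioning_on_irrelevant_marker_changes_nothing(self):
        cfg, G, ph = self.one_locus_panel()
        base = run_gwas(G, ph, response="quantitative")
        far = G.markers[(G.markers["chrom"].astype(str) == "2")].iloc[10]
        cond = conditional_scan(
            G, ph, [(far["chrom"], int(far["pos"]))], response="quantitative"
        )
        merged = base.table.merge(
            cond.table, on=["chrom", "pos"], suffixes=("_b", "_c")
        ).dropna(subset=["minus_log10_p_b", "minus_log10_p_c"])
        r = np.corrcoef(merged["minus_log10_p_b"], merged["minus_log10_p_c"])[0, 1]
        assert r > 0.99

    def test_constant_covariate_column_dropped(self):
        cfg, G, ph = self.one_locus_panel()
        j = 5
        G.dosage[:, j] = 2.0
        marker = (G.markers["chrom"].iloc[j], int(G.markers["pos"].iloc[j]))
        cond = conditional_scan(G, ph, [marker], response="quantitative")
        assert len(cond.table) > 0  # covariate dropped by collinearity screen

    def test_all_missing_covariate_rejected(self):
        cfg, G, ph = self.one_locus_panel()
        j = 7
        G.dosage[:, j] = np.nan
        marker = (G.markers["chrom"].iloc[j], int(G.markers["pos"].iloc[j]))
        with pytest.raises(ValueError, match="no genotype calls"):
            conditional_scan(G, ph, [marker], response="quantitative")


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert adjust_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (adjust_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_missing_p_excluded_from_m(self):
        q = adjust_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], [0.02, 0.02])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_brute_force(self, pvals):
        assert np.allclose(adjust_fdr(pvals), brute_force_bh(pvals), atol=1e-12)


class TestFdrThreshold:
    def make_result(self, p):
        p = np.asarray(p, dtype=float)
        table = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, len(p) + 1) * 100,
                "ref": "A",
                "alt": "T",
                "p": p,
                "minus_log10_p": -np.log10(p),
                "q": adjust_fdr(p),
            }
        )
        return AssociationResult(table=table)

    def test_no_rejection_line_above_max(self):
        res = self.make_result([0.2, 0.5, 0.9])
        line = fdr_threshold(res, 0.05)
        assert line > res.table["minus_log10_p"].max()
        assert (res.table["minus_log10_p"] >= line).sum() == 0

    def test_step_up_boundary_by_hand(self):
        p = np.concatenate([np.full(10, 1e-6), np.full(990, 0.5)])
        res = self.make_result(p)
        line = fdr_threshold(res, 0.05)
        assert line == pytest.approx(6.0)
        assert (res.table["minus_log10_p"] >= line).sum() == 10

    def test_threshold_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(1e-8, 1e-4, 20), rng.uniform(0, 1, 500)])
        res = self.make_result(p)
        assert fdr_threshold(res, 0.01) >= fdr_threshold(res, 0.05)
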