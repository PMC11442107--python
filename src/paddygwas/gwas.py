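"""Mixed-model association scans for an inbred panel.

The random effect is a polygenic term u ~ N(0, τK) with K the genomic
relationship matrix (GRM) from standardised dosages. Two response models are
provided:

* quantitative — the Gaussian linear mixed model y = Xβ + u + e,
  e ~ N(0, σ²I), variance components by REML profiled over λ = τ/σ² via the
  eigendecomposition of K;
* binary — a logistic linear mixed model logit P(y=1) = Xβ + u fitted by
  penalized quasi-likelihood (PQL): iterate a working LMM on the adjusted
  response z = η + (y−μ)/(μ(1−μ)) with working covariance Σ = τK + W⁻¹,
  W = diag(μ(1−μ)), re-estimating τ by working REML each step.

Per-marker tests are score tests with variance components held at their
null estimates (the fast mixed-model GWAS strategy): for marker dosage g,
T = g'r with r the null GLS/working residual, Var(T) = g'Pg where
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹, and T²/Var(T) ~ χ²₁ under the null. At
τ = 0 the binary version reduces exactly to the classic logistic-regression
score test.

No principal components enter the fixed effects by default (appropriate for
an unstructured panel); covariate genotypes can be appended for conditional
scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix over accessions (symmetric, PSD)."""

    values: np.ndarray
    accession_ids: list[str]

    def take(self, ids) -> "KinshipMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        idx = np.array([lookup[a] for a in ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids))


@dataclass
class NullModelFit:
    """Converged null model ready for score testing."""

    response: str
    accession_ids: list[str]
    X: np.ndarray
    beta: np.ndarray
    tau: float
    sigma2: float  # residual variance (1.0 for binary PQL working model)
    P: np.ndarray  # projection V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1
    resid: np.ndarray  # GLS residual (quantitative) or y - mu (binary)
    mu: np.ndarray
    converged: bool
    n_iter: int
    dropped_columns: list[int] = field(default_factory=list)


def compute_grm(G: GenotypeMatrix) -> KinshipMatrix:
    """GRM from standardised dosages: K = Z Z' / m with
    z = (x − 2p)/√(2p(1−p)), p the alt-allele frequency.

    Missing dosages are mean-imputed; monomorphic markers are skipped (count
    logged). Errors if every marker is monomorphic.
    """
    if G.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    X = G.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_skip = int((~poly).sum())
    if n_skip:
        logger.info("compute_grm: skipped %d monomorphic markers", n_skip)
    if not poly.any():
        raise ValueError("all markers monomorphic")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    K = Z @ Z.T / Z.shape[1]
    return KinshipMatrix((K + K.T) / 2.0, list(G.accession_ids))


def _drop_collinear(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Greedily drop columns that do not increase the rank."""
    keep: list[int] = []
    dropped: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(j)
    if dropped:
        logger.info("dropped %d collinear fixed-effect columns: %s", len(dropped), dropped)
    return X[:, keep], dropped


def _reml_quantitative(y, X, K) -> tuple[float, float, float]:
    """REML for y = Xβ + u + e via eigendecomposition of K.

    Profiles σ² out and maximises the restricted likelihood over
    λ = τ/σ² ≥ 0 on a log grid refined by Brent. Returns (τ, σ², λ)."""
    n, q = X.shape
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(log_lam):
        lam = np.exp(log_lam)
        d = lam * w + 1.0
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        beta = np.linalg.solve(XtVX, Xd.T @ yt)
        r = yt - Xt @ beta
        quad = float(r @ (r / d))
        sigma2 = quad / (n - q)
        ll = -0.5 * (
            (n - q) * np.log(sigma2)
            + np.sum(np.log(d))
            + np.linalg.slogdet(XtVX)[1]
            + (n - q)
        )
        return -ll

    grid = np.linspace(-10, 10, 41)
    vals = [neg_restricted_ll(g) for g in grid]
    gbest = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(gbest - 1.0, gbest + 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    # boundary check: lambda -> 0 (no polygenic component)
    if neg_restricted_ll(np.log(1e-12)) < res.fun:
        lam = 0.0
    d = lam * w + 1.0
    Xd = Xt / d[:, None]
    XtVX = Xt.T @ Xd
    beta = np.linalg.solve(XtVX, Xd.T @ yt)
    r = yt - Xt @ beta
    sigma2 = float(r @ (r / d)) / (n - q)
    return lam * sigma2, sigma2, lam


def _projection(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    Vinv = np.linalg.inv(V)
    VX = Vinv @ X
    return Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)


def fit_null_model(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: KinshipMatrix,
    response: str = "binary",
    accession_ids: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    fix_tau: float | None = None,
) -> NullModelFit:
    """Fit the null (no-marker) mixed model for score testing.

    ``y`` must be aligned with ``K.accession_ids`` (no missing values; drop
    unphenotyped accessions upstream). ``covariates`` is an optional n x c
    matrix appended to the intercept; collinear columns are dropped and
    logged. ``fix_tau`` pins the polygenic variance instead of estimating it
    (``fix_tau=0`` reduces the binary model to plain logistic regression and
    the quantitative model to OLS; for the quantitative model a nonzero
    value is interpreted as the ratio τ/σ²).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.values.shape[0] != n:
        raise ValueError("kinship not aligned with phenotype")
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values; drop them first")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    ids = accession_ids if accession_ids is not None else list(K.accession_ids)
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    X, dropped = _drop_collinear(X)

    if response == "quantitative":
        if fix_tau is not None:
            tau = float(fix_tau)
            V0 = tau * K.values + np.eye(n)
            Vinv0 = np.linalg.inv(V0)
            b0 = np.linalg.solve(X.T @ Vinv0 @ X, X.T @ Vinv0 @ y)
            r0 = y - X @ b0
            sigma2 = float(r0 @ Vinv0 @ r0) / (n - X.shape[1])
            tau = tau * sigma2
        else:
            tau, sigma2, _lam = _reml_quantitative(y, X, K.values)
        V = tau * K.values + sigma2 * np.eye(n)
        P = _projection(V, X)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        resid = P @ y  # equals V^-1 (y - X beta_gls)
        mu = X @ beta
        return NullModelFit(
            response, ids, X, beta, tau, sigma2, P, resid, mu, True, 1, dropped
        )

    if response != "binary":
        raise ValueError("response must be 'binary' or 'quantitative'")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary response must be coded 0/1")

    # PQL: working LMM on the adjusted response, tau by working REML
    eta = np.full(n, np.log((y.mean() + 0.5 / n) / (1 - y.mean() + 0.5 / n)))
    beta = None
    tau = 0.1
    converged = False
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-6, 1 - 1e-6)
        W = mu * (1 - mu)
        z = eta + (y - mu) / W

        if fix_tau is not None:
            tau = float(fix_tau)
        else:

            def neg_working_reml(log_tau):
                t = np.exp(log_tau)
                V = t * K.values + np.diag(1.0 / W)
                _, logdetV = np.linalg.slogdet(V)
                Vinv = np.linalg.inv(V)
                XtVX = X.T @ Vinv @ X
                b = np.linalg.solve(XtVX, X.T @ Vinv @ z)
                r = z - X @ b
                return 0.5 * (logdetV + np.linalg.slogdet(XtVX)[1] + r @ Vinv @ r)

            grid = np.linspace(-8, 6, 15)
            vals = [neg_working_reml(g) for g in grid]
            gbest = grid[int(np.argmin(vals))]
            res = minimize_scalar(
                neg_working_reml,
                bounds=(gbest - 1.0, gbest + 1.0),
                method="bounded",
                options={"xatol": 1e-8},
            )
            tau = float(np.exp(res.x))
        V = tau * K.values + np.diag(1.0 / W)
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        beta = np.linalg.solve(XtVX, X.T @ Vinv @ z)
        r = z - X @ beta
        u = tau * (K.values @ (Vinv @ r))
        eta_new = X @ beta + u
        delta = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"PQL did not converge in {max_iter} iterations (last delta {delta:.3g})"
        )
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = np.clip(mu * (1 - mu), 1e-12, None)
    V = tau * K.values + np.diag(1.0 / W)
    P = _projection(V, X)
    return NullModelFit(
        "binary", ids, X, beta, tau, 1.0, P, y - mu, mu, True, it, dropped
    )


def association_scan(
    G: GenotypeMatrix,
    null_fit: NullModelFit,
    exclude: set | None = None,
) -> "AssociationResult":
    """Score-test every marker against the fitted null model.

    Missing dosages are mean-imputed per marker so every test uses the full
    accession set. Markers with zero dosage variance after imputation get a
    missing p (logged). ``exclude`` is a set of (chrom, pos) left out of the
    scan (used for conditional covariate markers).
    """
    if list(G.accession_ids) != list(null_fit.accession_ids):
        G = G.take_accessions(null_fit.accession_ids)
    Ximp = G.imputed()
    P, r = null_fit.P, null_fit.resid

    num = Ximp.T @ r  # g' resid
    PG = P @ Ximp
    den = np.einsum("ij,ij->j", Ximp, PG)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = num**2 / den
        effect = num / den
    var0 = Ximp.var(axis=0)
    bad = (var0 <= 0) | (den <= 0)
    if bad.any():
        logger.info("association_scan: %d zero-variance markers set missing", int(bad.sum()))
    stat[bad] = np.nan
    effect[bad] = np.nan
    p = chi2.sf(stat, df=1)
    if exclude:
        excl = {(str(c), int(p)) for c, p in exclude}
        mask = np.array(
            [(str(c), int(pp)) in excl for c, pp in zip(G.markers["chrom"], G.markers["pos"])]
        )
        keep = ~mask
    else:
        keep = np.ones(G.n_markers, dtype=bool)

    table = G.markers.loc[keep, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    table["effect"] = effect[keep]
    table["stat"] = stat[keep]
    table["p"] = p[keep]
    with np.errstate(divide="ignore"):
        table["minus_log10_p"] = -np.log10(table["p"])
    table["q"] = adjust_fdr(table["p"].to_numpy())
    model = f"{null_fit.response} LMM score test (tau={null_fit.tau:.4g})"
    result = AssociationResult(table=table, model=model)
    result.sug_line = fdr_threshold(result, 0.05)
    result.sig_line = fdr_threshold(result, 0.01)
    return result


@dataclass
class AssociationResult:
    """Per-marker association results plus the BH-FDR threshold lines."""

    table: pd.DataFrame
    model: str = ""
    sug_line: float = np.nan  # -log10(p) at FDR 0.05
    sig_line: float = np.nan  # -log10(p) at FDR 0.01


def align_phenotype(
    G: GenotypeMatrix, pheno: pd.DataFrame, K: KinshipMatrix
) -> tuple[GenotypeMatrix, np.ndarray, KinshipMatrix]:
    """Drop unphenotyped accessions and align G, y and K on the same order."""
    ph = pheno.dropna(subset=["trait"]).set_index("accession_id")["trait"]
    ids = [a for a in G.accession_ids if a in ph.index]
    if not ids:
        raise ValueError("no phenotyped accessions in genotype matrix")
    return G.take_accessions(ids), ph.loc[ids].to_numpy(dtype=float), K.take(ids)


def run_gwas(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    K: KinshipMatrix | None = None,
    response: str = "binary",
) -> AssociationResult:
    """Null fit + genome scan in one call (no conditional covariates)."""
    if K is None:
        K = compute_grm(G)
    Ga, y, Ka = align_phenotype(G, pheno, K)
    null = fit_null_model(y, None, Ka, response=response)
    return association_scan(Ga, null)


def conditional_scan(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariate_markers: list[tuple],
    K: KinshipMatrix | None = None,
    response: str = "quantitative",
) -> AssociationResult:
    """Scan with named marker genotypes as fixed-effect covariates.

    The covariate markers themselves are excluded from the scan. A covariate
    marker with all-missing genotypes raises; a constant covariate column is
    dropped by the collinearity screen (logged). The default response is
    quantitative (the Gaussian LMM on the 0/1 coding), the fallback used when
    the logistic conditional model shows genome-wide p-value inflation.
    """
    if K is None:
        K = compute_grm(G)
    Ga, y, Ka = align_phenotype(G, pheno, K)
    cols = []
    for chrom, pos in covariate_markers:
        gcol = Ga.dosage[:, Ga.marker_index(chrom, pos)]
        if np.isnan(gcol).all():
            raise ValueError(f"covariate marker {chrom}:{pos} has no genotype calls")
        gimp = np.where(np.isnan(gcol), np.nanmean(gcol), gcol)
        cols.append(gimp)
    C = np.column_stack(cols)
    null = fit_null_model(y, C, Ka, response=response)
    exclude = {(c, int(p)) for c, p in covariate_markers}
    return association_scan(Ga, null, exclude=exclude)


def adjust_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg q-values; missing p-values stay missing and do not
    count toward m."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def fdr_threshold(result: AssociationResult, alpha: float) -> float:
    """The −log10(p) rejection boundary at FDR level ``alpha``.

    This is the −log10 of the largest p whose BH q-value is ≤ alpha — the
    horizontal line of a Manhattan plot. When no marker is rejected the line
    is placed above the maximum observed score (max + 1), so zero markers sit
    on or above it.
    """
    t = result.table
    ok = t.dropna(subset=["p", "q"])
    rej = ok[ok["q"] <= alpha]
    if len(rej) == 0:
        m = ok["minus_log10_p"].max()
        return float(m + 1.0) if np.isfinite(m) else np.inf
    return float(-np.log10(rej["p"].max()))
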