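"""Linkage-disequilibrium decay: pair sampling, r², and the extended
Hill–Weir hyperbolic decay fit.

The decay model is

    E[r²](d) = (r²_high − r²_low) / (1 + d·r_d) + r²_low

with d the inter-marker distance in bp, r²_high / r²_low the maximum /
minimum observed r² asymptotes and r_d the decay rate (1/bp). The distance
at which the curve reaches the midpoint of its asymptotes is d_LD50 = 1/r_d
exactly — substituting d = 1/r_d makes the hyperbolic term (r²_high −
r²_low)/2.

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete accessions; for fully inbred lines (hets masked) this
equals haplotype r², so no EM phasing is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDDecayModel:
    """Fitted decay parameters for one chromosome (or pooled "genome")."""

    r2_high: float
    r2_low: float
    r_d: float
    chromosome: object = "genome"
    rss: float = np.nan
    n_pairs: int = 0
    identifiable: bool = True

    @property
    def d_ld50(self) -> float:
        return d_ld50(self)

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return (self.r2_high - self.r2_low) / (1.0 + d * self.r_d) + self.r2_low


def sample_marker_pairs(
    G: GenotypeMatrix,
    n_pairs: int,
    max_dist: int = 10_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample same-chromosome marker pairs separated by at most ``max_dist``.

    Pairs are drawn uniformly without replacement from the implicit space of
    eligible pairs (never materialised); if fewer eligible pairs exist than
    requested, all are returned. Columns: chrom, i, j (column indices into
    G), d (bp).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    chrom_arr = G.markers["chrom"].to_numpy()
    pos_arr = G.markers["pos"].to_numpy()

    # per-marker count of eligible partners to the right, per chromosome
    blocks = []  # (offset into flat pair space, chrom, local positions, counts)
    total = 0
    for c in pd.unique(chrom_arr):
        sel = np.flatnonzero(chrom_arr == c)
        pos = pos_arr[sel]
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        counts = hi - np.arange(len(pos)) - 1  # partners j>i within max_dist
        csum = int(counts.sum())
        if csum > 0:
            blocks.append((total, c, sel, pos, counts))
            total += csum
    if total == 0:
        raise ValueError("no eligible marker pairs")

    rng = np.random.default_rng(seed)
    if n_pairs >= total:
        flat = np.arange(total, dtype=np.int64)
    else:
        # rejection sampling without replacement over the flat index space
        chosen: set = set()
        while len(chosen) < n_pairs:
            draw = rng.integers(0, total, size=n_pairs - len(chosen))
            chosen.update(draw.tolist())
        flat = np.sort(np.fromiter(chosen, dtype=np.int64, count=len(chosen)))

    rows = {"chrom": [], "i": [], "j": [], "d": []}
    for offset, c, sel, pos, counts in blocks:
        csum = int(counts.sum())
        local = flat[(flat >= offset) & (flat < offset + csum)] - offset
        if local.size == 0:
            continue
        starts = np.concatenate([[0], np.cumsum(counts)])
        ii = np.searchsorted(starts, local, side="right") - 1
        jj = ii + 1 + (local - starts[ii])
        rows["chrom"].extend([c] * len(ii))
        rows["i"].extend(sel[ii].tolist())
        rows["j"].extend(sel[jj].tolist())
        rows["d"].extend((pos[jj] - pos[ii]).tolist())
    return pd.DataFrame(rows)


def pairwise_r2(G: GenotypeMatrix, pairs: pd.DataFrame, chunk: int = 8192) -> pd.DataFrame:
    """Fill the ``r2`` column: squared Pearson correlation of the two dosage
    vectors over accessions non-missing at both markers.

    Pairs with fewer than 2 informative accessions or a monomorphic vector
    are dropped (count logged).
    """
    X = G.dosage
    i_all = pairs["i"].to_numpy()
    j_all = pairs["j"].to_numpy()
    r2 = np.full(len(pairs), np.nan)
    for lo in range(0, len(pairs), chunk):
        hi = min(lo + chunk, len(pairs))
        a = X[:, i_all[lo:hi]]
        b = X[:, j_all[lo:hi]]
        valid = ~(np.isnan(a) | np.isnan(b))
        n = valid.sum(axis=0)
        a0 = np.where(valid, a, 0.0)
        b0 = np.where(valid, b, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ma = a0.sum(axis=0) / n
            mb = b0.sum(axis=0) / n
            sab = (a0 * b0).sum(axis=0) - n * ma * mb
            saa = (a0 * a0).sum(axis=0) - n * ma * ma
            sbb = (b0 * b0).sum(axis=0) - n * mb * mb
            val = (sab * sab) / (saa * sbb)
        val[(n < 2) | (saa <= 0) | (sbb <= 0)] = np.nan
        r2[lo:hi] = val
    out = pairs.copy()
    out["r2"] = np.clip(r2, 0.0, 1.0)
    n_drop = int(np.isnan(r2).sum())
    if n_drop:
        logger.info("pairwise_r2: dropped %d uninformative pairs", n_drop)
    return out.dropna(subset=["r2"]).reset_index(drop=True)


def _model(params, d):
    delta, r2_low, r_d = params
    return delta / (1.0 + d * r_d) + r2_low


def fit_decay_model(
    sample: pd.DataFrame,
    chromosome: object = "genome",
    max_restarts: int = 5,
    flat_tol: float = 1e-9,
) -> LDDecayModel:
    """Nonlinear least squares of the hyperbolic decay model.

    Parametrised internally as (delta = r²_high − r²_low, r²_low, r_d) with
    box constraints delta, r²_low in [0, 1] and r_d > 0, which enforces
    0 ≤ r²_low ≤ r²_high. Initialisation: r²_high from the mean r² of the
    closest 1% of distances, r²_low from the farthest 1%, r_d = 1/median(d);
    up to ``max_restarts`` jittered restarts on failure. A fit with
    delta ≈ 0 (flat curve) is flagged ``identifiable=False`` — r_d carries
    no information there.
    """
    d = sample["d"].to_numpy(dtype=float)
    r2 = sample["r2"].to_numpy(dtype=float)
    if len(d) < 3 or len(np.unique(d)) < 2:
        raise ValueError("need >=3 pairs with >=2 distinct distances")

    order = np.argsort(d)
    k = max(1, len(d) // 100)
    high0 = float(np.mean(r2[order[:k]]))
    low0 = float(np.mean(r2[order[-k:]]))
    if high0 < low0:
        high0, low0 = low0, high0
    x0 = np.array([max(high0 - low0, 1e-3), np.clip(low0, 0, 1), 1.0 / np.median(d)])
    lb = np.array([0.0, 0.0, 1e-15])
    ub = np.array([1.0, 1.0, np.inf])

    rng = np.random.default_rng(12345)
    best = None
    last_err = None
    for attempt in range(max_restarts + 1):
        x_init = x0 if attempt == 0 else np.clip(
            x0 * np.exp(rng.normal(0, 0.5, size=3)), lb + 1e-12, [1, 1, 1e6]
        )
        try:
            res = least_squares(
                lambda p: _model(p, d) - r2,
                x_init,
                bounds=(lb, ub),
                x_scale="jac",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            last_err = exc
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            break
    if best is None:
        raise RuntimeError(f"decay fit failed after restarts: {last_err}")
    delta, r2_low, r_d = best.x
    return LDDecayModel(
        r2_high=float(delta + r2_low),
        r2_low=float(r2_low),
        r_d=float(r_d),
        chromosome=chromosome,
        rss=float(2 * best.cost),
        n_pairs=len(d),
        identifiable=bool(delta > flat_tol),
    )


def d_ld50(model: LDDecayModel) -> float:
    """d_LD50 = 1/r_d; verifies the midpoint identity of the fitted curve."""
    if model.r_d <= 0:
        raise ValueError("r_d must be positive")
    d = 1.0 / model.r_d
    mid = (model.r2_high + model.r2_low) / 2.0
    assert np.isclose(model.predict(d), mid, rtol=0, atol=1e-12 + 1e-9 * abs(mid))
    return d


def genome_wide_d_ld50(models: list[LDDecayModel]) -> float:
    """Arithmetic mean of the per-chromosome d_LD50 values."""
    if not models:
        raise ValueError("no chromosome models")
    return float(np.mean([d_ld50(m) for m in models]))


def estimate_ld_decay(
    G: GenotypeMatrix,
    n_pairs: int = 500_000,
    max_dist: int = 10_000_000,
    seed: int = 0,
) -> tuple[list[LDDecayModel], float]:
    """Genome-wide pair sampling, per-chromosome decay fits, averaged d_LD50.

    Pairs are sampled once across the genome and split by chromosome for
    fitting; chromosomes with too few pairs for a fit are skipped (logged).
    Returns (per-chromosome models, genome-wide d_LD50).
    """
    pairs = pairwise_r2(G, sample_marker_pairs(G, n_pairs, max_dist, seed))
    models = []
    for c, sub in pairs.groupby("chrom", sort=False):
        try:
            models.append(fit_decay_model(sub, chromosome=c))
        except ValueError:
            logger.warning("chromosome %s skipped: too few informative pairs", c)
    return models, genome_wide_d_ld50(models)
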