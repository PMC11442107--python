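"""Genotype matrix container, VCF input and the marker-level post-filters.

The panel is a set of (nearly) fully inbred accessions, so genotypes are
alt-allele dosages in {0, 2} with residual heterozygous calls treated as
noise: the pipeline's first post-filter sets every het call to missing, the
convention used when a germline caller is run on inbred material.

Coordinates are 1-based (VCF convention). Window arithmetic (pruning) uses
0-based half-open bins internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Accessions x markers alt-allele dosage with a missing mask.

    Attributes
    ----------
    accession_ids : list of str
        Row labels, one per inbred accession.
    markers : pandas.DataFrame
        One row per marker with columns ``chrom, pos, ref, alt``; sorted by
        (chrom, pos) with unique positions per chromosome.
    dosage : numpy.ndarray, float, shape (n_accessions, n_markers)
        Alt-allele count in {0, 1, 2}; missing calls are NaN.
    """

    accession_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        n, m = self.dosage.shape
        if n != len(self.accession_ids):
            raise ValueError("dosage rows != number of accessions")
        if m != len(self.markers):
            raise ValueError("dosage columns != number of markers")
        self._check_sorted_unique()

    def _check_sorted_unique(self) -> None:
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"markers on {c} not sorted/unique by position")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.markers["chrom"]))

    def marker_index(self, chrom, pos: int) -> int:
        """Column index of the marker at (chrom, pos); KeyError if absent.

        Chromosome labels compare as strings, so an int label round-tripped
        through VCF still resolves.
        """
        hit = np.flatnonzero(
            (self.markers["chrom"].astype(str).to_numpy() == str(chrom))
            & (self.markers["pos"].to_numpy() == pos)
        )
        if hit.size == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
        )

    def take_accessions(self, ids) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [lookup[a] for a in ids]
        return GenotypeMatrix(
            accession_ids=list(ids),
            markers=self.markers.copy(),
            dosage=self.dosage[rows, :].copy(),
        )

    def imputed(self) -> np.ndarray:
        """Dosage with missing calls replaced by the per-marker mean."""
        X = self.dosage.copy()
        n_obs = (~np.isnan(X)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(n_obs > 0, np.nansum(X, axis=0) / np.maximum(n_obs, 1), 0.0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = means[nan_c]
        return X


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are admitted; multi-allelic and indel records
    are skipped (the skipped count is logged). ``./.`` genotypes become NaN.
    Raises ``ValueError`` on unsorted input or duplicated positions.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    skipped = 0
    last: dict = {}
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        prev = last.get(rec.CHROM)
        if prev is not None and rec.POS <= prev:
            raise ValueError(
                f"unsorted or duplicated position {rec.CHROM}:{rec.POS}"
            )
        last[rec.CHROM] = rec.POS
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        d = np.full(len(samples), np.nan)
        d[gt == 0] = 0.0
        d[gt == 1] = 1.0
        d[gt == 3] = 2.0
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        dosages.append(d)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return GenotypeMatrix(samples, markers, np.column_stack(dosages) if dosages else np.empty((len(samples), 0)))


def mask_heterozygotes(G: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Set every heterozygous call (dosage 1) to missing.

    Returns the new matrix and the number of calls masked. Homozygous calls
    are untouched.
    """
    het = G.dosage == 1.0
    n_masked = int(het.sum())
    X = G.dosage.copy()
    X[het] = np.nan
    return GenotypeMatrix(list(G.accession_ids), G.markers.copy(), X), n_masked


def compute_marker_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, missing rate and het rate.

    MAF is min(p, 1-p) with p the mean dosage over non-missing calls divided
    by 2. A marker with zero non-missing calls gets NaN MAF and is flagged in
    the ``undefined`` column.
    """
    X = G.dosage
    n = X.shape[0]
    n_missing = np.isnan(X).sum(axis=0)
    n_obs = n - n_missing
    alt_sum = np.nansum(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt_sum / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    het_rate = np.where(n_obs > 0, (X == 1.0).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame(
        {
            "maf": maf,
            "missing_rate": n_missing / n,
            "het_rate": het_rate,
            "undefined": n_obs == 0,
        }
    )


def filter_markers(
    G: GenotypeMatrix,
    stats: pd.DataFrame,
    maf_min: float = 0.05,
    miss_max: float = 0.20,
) -> GenotypeMatrix:
    """Retain markers with MAF strictly above ``maf_min`` and missing rate at
    most ``miss_max`` ("more than 5% MAF, less than or equal to 20% missing").
    Marker order is preserved; undefined-MAF markers are always dropped.
    """
    if len(stats) != G.n_markers:
        raise ValueError("stats not aligned with genotype matrix")
    keep = (
        (stats["maf"].to_numpy() > maf_min)
        & (stats["missing_rate"].to_numpy() <= miss_max)
        & ~stats["undefined"].to_numpy()
    )
    return G.take_markers(np.flatnonzero(keep))


def prune_by_window(
    G: GenotypeMatrix,
    window_bp: int,
    stats: pd.DataFrame | None = None,
    policy: str = "lowest_missing",
) -> GenotypeMatrix:
    """Keep one marker per non-overlapping ``window_bp`` stretch.

    Chromosomes are partitioned into 0-based half-open bins
    ``[k*window_bp, (k+1)*window_bp)`` anchored at position 0; within each
    non-empty bin one marker survives. ``policy`` is "lowest_missing"
    (lowest missing rate, ties broken by lowest position) or "first".
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if stats is None:
        stats = compute_marker_stats(G)
    df = G.markers.copy()
    df["idx"] = np.arange(len(df))
    df["missing_rate"] = stats["missing_rate"].to_numpy()
    df["bin"] = (df["pos"].to_numpy() - 1) // window_bp
    keep = []
    for (_, _), grp in df.groupby(["chrom", "bin"], sort=False):
        if policy == "first":
            keep.append(int(grp["idx"].iloc[0]))
        else:
            best = grp.sort_values(["missing_rate", "pos"]).iloc[0]
            keep.append(int(best["idx"]))
    keep.sort()
    return G.take_markers(keep)
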