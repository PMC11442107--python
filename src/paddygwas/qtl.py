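"""QTL-region calling and peak characterisation.

A QTL region is a window of +/- one d_LD50 around a peak association marker
that (a) contains at least one marker above the significant FDR line and
(b) contains at least two markers above the suggestive line (the peak counts
toward the two) — an isolated significant spike never becomes a region.
Overlap resolution is greedy and peak-first: the strongest unclaimed
significant marker founds each candidate window, and every in-window marker
is claimed whether or not the candidate is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import AssociationResult
from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QTLRegion:
    """One called region around a peak association marker."""

    name: str
    chromosome: object
    peak_pos: int
    peak_ref: str
    peak_alt: str
    peak_minus_log10_p: float
    window: tuple  # (lo, hi) bp, peak +/- the d_LD50 window used
    supporting_markers: list = field(default_factory=list)  # positions above sug line
    n_significant: int = 0

    def validate(self) -> None:
        if self.n_significant < 1:
            raise AssertionError("region without a significant marker")
        if len(self.supporting_markers) < 2:
            raise AssertionError("region with a lone suggestive marker")
        if not (self.window[0] <= self.peak_pos <= self.window[1]):
            raise AssertionError("peak outside its window")


def call_qtl_regions(
    result: AssociationResult,
    window_bp: float,
    sig_line: float | None = None,
    sug_line: float | None = None,
    trait: str = "APC",
) -> list[QTLRegion]:
    """Apply the dual-threshold, d_LD50-window region definition.

    Per chromosome: repeatedly take the unclaimed marker with the highest
    score above ``sig_line`` (ties: lower position), collect markers within
    ±``window_bp``, accept the candidate iff ≥2 in-window markers exceed
    ``sug_line`` (peak included), and claim the whole window either way.
    Regions are named q<trait><chrom>.<ordinal> in positional order per
    chromosome. Thresholds default to the result's FDR lines.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    sig = result.sig_line if sig_line is None else sig_line
    sug = result.sug_line if sug_line is None else sug_line
    if sig < sug:
        raise ValueError("significant line must be >= suggestive line")

    regions: list[QTLRegion] = []
    t = result.table.dropna(subset=["minus_log10_p"])
    for chrom, sub in t.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        score = sub["minus_log10_p"].to_numpy()
        claimed = np.zeros(len(sub), dtype=bool)
        while True:
            cand = np.flatnonzero(~claimed & (score >= sig))
            if cand.size == 0:
                break
            # highest score, ties -> lower position
            best = cand[np.lexsort((pos[cand], -score[cand]))[0]]
            lo, hi = pos[best] - window_bp, pos[best] + window_bp
            inwin = np.flatnonzero((pos >= lo) & (pos <= hi))
            support = inwin[score[inwin] >= sug]
            n_sig = int((score[inwin] >= sig).sum())
            if len(support) >= 2:
                regions.append(
                    QTLRegion(
                        name="",
                        chromosome=chrom,
                        peak_pos=int(pos[best]),
                        peak_ref=str(sub["ref"].iloc[best]),
                        peak_alt=str(sub["alt"].iloc[best]),
                        peak_minus_log10_p=float(score[best]),
                        window=(int(lo), int(hi)),
                        supporting_markers=[int(p) for p in pos[support]],
                        n_significant=n_sig,
                    )
                )
            claimed[inwin] = True

    regions.sort(key=lambda r: (str(r.chromosome), r.peak_pos))
    per_chrom: dict = {}
    for r in regions:
        per_chrom[r.chromosome] = per_chrom.get(r.chromosome, 0) + 1
        r.name = f"q{trait}{r.chromosome}.{per_chrom[r.chromosome]}"
        r.validate()
    return regions


def peak_genotype_correlations(
    G: GenotypeMatrix, regions: list[QTLRegion]
) -> pd.DataFrame:
    """QTL x QTL Pearson correlations between peak-marker dosage vectors.

    Complete-case per pair; the diagonal is the self-correlation (1.000 for
    any polymorphic peak). A monomorphic peak yields NaN entries (flagged in
    the log).
    """
    names = [r.name for r in regions]
    cols = [G.dosage[:, G.marker_index(r.chromosome, r.peak_pos)] for r in regions]
    k = len(cols)
    M = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            x, y = cols[a], cols[b]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                logger.warning(
                    "undefined peak correlation between %s and %s", names[a], names[b]
                )
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            M[a, b] = M[b, a] = r
    return pd.DataFrame(M, index=names, columns=names)


def local_ld_matrix(
    G: GenotypeMatrix, region: QTLRegion, flank_bp: int = 0
) -> pd.DataFrame:
    """Pairwise r² among all markers in the region window (± ``flank_bp``).

    Same estimator as the decay scan: squared Pearson correlation over
    pairwise-complete accessions. Returned with positions as labels for
    heatmap plotting; symmetric with unit diagonal.
    """
    chrom = G.markers["chrom"].astype(str).to_numpy()
    pos = G.markers["pos"].to_numpy()
    lo, hi = region.window[0] - flank_bp, region.window[1] + flank_bp
    idx = np.flatnonzero((chrom == str(region.chromosome)) & (pos >= lo) & (pos <= hi))
    if idx.size < 2:
        raise ValueError("fewer than 2 markers in region window")
    labels = [int(p) for p in pos[idx]]
    k = idx.size
    M = np.full((k, k), np.nan)
    X = G.dosage[:, idx]
    for a in range(k):
        M[a, a] = 1.0
        for b in range(a + 1, k):
            x, y = X[:, a], X[:, b]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            M[a, b] = M[b, a] = r * r
    return pd.DataFrame(M, index=labels, columns=labels)


def genes_in_region(annotation_path: str, region: QTLRegion) -> pd.DataFrame:
    """Genes from a GFF3 whose span intersects the region window.

    Coordinates are 1-based inclusive (GFF3). Reports each overlapping gene
    with its distance from the peak marker (0 when the peak lies inside the
    gene), sorted by distance. Raises if the region's chromosome is absent
    from the annotation, listing both name sets.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gff_chroms = {f.seqid for f in db.all_features()}
    target = str(region.chromosome)
    if target not in gff_chroms:
        raise ValueError(
            f"chromosome {target!r} not in annotation "
            f"(annotation has {sorted(gff_chroms)})"
        )
    lo, hi = region.window
    rows = []
    for f in db.all_features(featuretype="gene"):
        if f.seqid != target or f.end < lo or f.start > hi:
            continue
        if f.start <= region.peak_pos <= f.end:
            dist = 0
        else:
            dist = min(abs(f.start - region.peak_pos), abs(f.end - region.peak_pos))
        rows.append(
            {
                "gene_id": f.id,
                "chrom": f.seqid,
                "start": f.start,
                "end": f.end,
                "distance_from_peak": dist,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "distance_from_peak"]
    ).sort_values(["distance_from_peak", "start"]).reset_index(drop=True)
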