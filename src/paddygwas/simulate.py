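"""Synthetic inbred diversity panel: genotypes, binary trait, origins.

The generator emulates the statistical structure of a panel of ~250 fully
inbred rice accessions drawn from one unstructured gene pool:

* genotypes are founder-haplotype mosaics (a hidden-Markov copying process)
  so intra-chromosomal LD decays genuinely with physical distance, governed
  by one interpretable parameter, the per-bp founder-switch rate;
* the binary apiculus-colour trait is controlled by one major
  loss-of-function locus with near-complete penetrance plus two complementary
  modifier loci (an accession carrying the functional major allele is
  colourless only when alt-homozygous at BOTH modifiers);
* geographic origins give genotype PC1 a configurable weak correlation with
  latitude, with seven latitude-band region labels.

All stages draw from per-stage random streams derived from one master seed,
so each stage can be regenerated independently and fixtures are
byte-identical across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MARKER_COLUMNS, GenotypeMatrix

_STAGE = {"genotypes": 0, "phenotype": 1, "origins": 2}

_NUC = np.array(list("ACGT"))

#: Region labels ordered south -> north along the latitude axis.
REGION_LABELS = ["DR", "WCR", "ECR", "CDZ", "EMR", "WMR", "NMR"]


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Stage stream: one master seed, fixed per-stage spawn keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE[stage],)))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic panel.

    Defaults follow the real panel's scale: 250 accessions, 12 chromosomes,
    MAF >= 5% markers, low missingness, loss-allele frequency at the major
    locus near 0.64 (161 of 250 loss-homozygotes), penetrance 159/161, and
    modifier allele frequencies near 0.26 so roughly 4 of the ~61 functional
    carriers are colourless through the complementary modifier pair.
    """

    n_accessions: int = 250
    n_chromosomes: int = 12
    chrom_length_bp: int = 30_000_000
    n_markers_per_chrom: int = 5_000
    n_founders: int = 20
    switch_rate: float = 1.25e-6  # calibrated: genome-wide d_LD50 ~ 1e5 bp
    founder_switch_rate: float | None = None  # default: switch_rate / 2
    oversample_factor: float = 1.5
    maf_min: float = 0.05
    missing_rate: float = 0.05
    het_injection_rate: float = 0.01
    major_locus: tuple = (6, 4_866_454)
    modifier_loci: tuple = ((8, 7_780_702), (12, 958_898))
    major_loss_freq: float = 161 / 250
    modifier_alt_freq: float = 0.26
    penetrance_major: float = 159 / 161
    leak_rate: float = 0.0
    geo_effect: float = 0.39
    geo_effect_lon: float = 0.22
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")
        for p in (self.penetrance_major, self.leak_rate, self.het_injection_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        # a founder carrier count c must exist with maf_min <= c/F <= 1-maf_min
        F = self.n_founders
        if int(np.ceil(self.maf_min * F)) > int(np.floor((1 - self.maf_min) * F)):
            raise ValueError(
                f"maf_min={self.maf_min} unattainable with {F} founders"
            )
        for chrom, pos in self.causal_loci():
            if not (1 <= chrom <= self.n_chromosomes):
                raise ValueError(f"causal locus on invalid chromosome {chrom}")
            if not (1 <= pos <= self.chrom_length_bp):
                raise ValueError(f"causal position {pos} outside chromosome")

    def causal_loci(self) -> list:
        return [tuple(self.major_locus)] + [tuple(m) for m in self.modifier_loci]


def _founder_pool(
    rng,
    F: int,
    pos: np.ndarray,
    switch_rate: float,
    forced: dict[int, float] | None = None,
) -> np.ndarray:
    """Founder haplotypes with internal LD from nested allele partitions.

    The chromosome is cut into ancestry segments (per-bp boundary rate
    ``switch_rate``). Within a segment a fixed random founder ordering
    holds and each marker's alt-carrier set is a random-length prefix of
    it, so carrier sets of nearby markers are nested — the D'=1 haplotype
    blocks that give a high short-range r² asymptote. Across segments the
    ordering is redrawn and partitions decorrelate. ``forced`` maps a marker
    index to a target alt frequency; the forced column keeps the segment's
    ordering (hence its local LD) and only pins the prefix length.
    """
    m = len(pos)
    boundary = np.empty(m, dtype=bool)
    boundary[0] = True
    gaps = np.diff(pos).astype(float)
    boundary[1:] = rng.random(m - 1) < 1.0 - np.exp(-switch_rate * gaps)
    seg_id = np.cumsum(boundary) - 1
    n_seg = int(seg_id[-1]) + 1
    # rank_arr[s, f] = position of founder f in segment s's ordering
    rank_arr = np.argsort(rng.random((n_seg, F)), axis=1).argsort(axis=1)
    c = rng.integers(1, F, size=m)  # prefix length = alt carrier count
    if forced:
        for idx, freq in forced.items():
            c[idx] = int(np.clip(round(freq * F), 1, F - 1))
    H = (rank_arr[seg_id, :] < c[:, None]).T.astype(np.int8)
    return H


def simulate_genotypes(config: SyntheticConfig) -> GenotypeMatrix:
    """Founder-mosaic inbred genotypes.

    Each accession's chromosome copies from ``n_founders`` founder haplotypes
    with a founder switch between adjacent markers occurring with probability
    ``1 - exp(-switch_rate * gap_bp)`` (geometric segment lengths). Dosages
    are homozygous (0/2) by construction; heterozygous calls and missing
    calls are injected afterwards at their configured rates (never at causal
    loci, which stay fully observed so the phenotype model is exercised on
    complete causal genotypes). Markers whose realised panel MAF falls below
    ``maf_min`` are dropped, causal loci excepted.
    """
    config.validate()
    rng = _rng(config.seed, "genotypes")
    n, F = config.n_accessions, config.n_founders
    causal = set(config.causal_loci())

    founder_switch = (
        config.founder_switch_rate
        if config.founder_switch_rate is not None
        else config.switch_rate / 2.0
    )
    all_markers = []
    all_dosage = []
    for chrom in range(1, config.n_chromosomes + 1):
        # oversample candidate sites: the MAF screen will thin them back
        m_draw = min(
            int(config.n_markers_per_chrom * config.oversample_factor),
            config.chrom_length_bp,
        )
        pos = np.sort(rng.choice(config.chrom_length_bp, size=m_draw, replace=False)) + 1
        forced = sorted(p for (c, p) in causal if c == chrom)
        if forced:
            pos = np.unique(np.concatenate([pos, np.array(forced, dtype=pos.dtype)]))
        m = len(pos)

        forced_idx = {p: int(np.searchsorted(pos, p)) for p in forced}
        forced_freqs = {}
        for (c, p), freq in zip(
            config.causal_loci(),
            [config.major_loss_freq, config.modifier_alt_freq, config.modifier_alt_freq],
        ):
            if c == chrom:
                forced_freqs[forced_idx[p]] = freq
        founder_alleles = _founder_pool(rng, F, pos, founder_switch, forced_freqs)

        # panel mosaic: switch indicator per (accession, marker gap)
        gaps = np.diff(pos).astype(float)
        p_switch = 1.0 - np.exp(-config.switch_rate * gaps)
        switch = np.empty((n, m), dtype=bool)
        switch[:, 0] = True
        switch[:, 1:] = rng.random((n, m - 1)) < p_switch[None, :]
        seg_id = np.cumsum(switch, axis=1) - 1
        founder_draws = rng.integers(0, F, size=(n, m))
        founder_at = np.take_along_axis(founder_draws, seg_id, axis=1)
        dosage = 2.0 * founder_alleles[founder_at, np.arange(m)[None, :]]

        # MAF screen on the realised panel frequencies (causal loci exempt),
        # then thin back to the requested marker count
        p_panel = dosage.mean(axis=0) / 2.0
        maf = np.minimum(p_panel, 1 - p_panel)
        keep = maf >= config.maf_min
        for p in forced:
            keep[forced_idx[p]] = True
        pos, dosage = pos[keep], dosage[:, keep]
        m = len(pos)
        protect = np.isin(pos, np.array(forced, dtype=pos.dtype)) if forced else np.zeros(m, bool)
        if m > config.n_markers_per_chrom:
            extra = np.flatnonzero(~protect)
            n_drop = m - config.n_markers_per_chrom
            drop = rng.choice(extra, size=n_drop, replace=False)
            keep2 = np.ones(m, dtype=bool)
            keep2[drop] = False
            pos, dosage, protect = pos[keep2], dosage[:, keep2], protect[keep2]
            m = len(pos)

        if config.het_injection_rate > 0:
            het = (rng.random((n, m)) < config.het_injection_rate) & ~protect[None, :]
            dosage[het] = 1.0
        if config.missing_rate > 0:
            miss = (rng.random((n, m)) < config.missing_rate) & ~protect[None, :]
            dosage[miss] = np.nan

        ref_idx = rng.integers(0, 4, size=m)
        ref = _NUC[ref_idx]
        alt = _NUC[(ref_idx + rng.integers(1, 4, size=m)) % 4]
        all_markers.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
        )
        all_dosage.append(dosage)

    markers = pd.concat(all_markers, ignore_index=True)
    accession_ids = [f"ACC{i:04d}" for i in range(1, n + 1)]
    return GenotypeMatrix(accession_ids, markers, np.concatenate(all_dosage, axis=1))


def simulate_phenotype(G: GenotypeMatrix, config: SyntheticConfig) -> pd.DataFrame:
    """Binary apiculus-colour phenotype (colourless = 1, coloured = 0).

    An accession is colourless iff (a) loss-homozygous at the major locus,
    with probability ``penetrance_major``; or (b) it carries the functional
    major allele but is alt-homozygous at both modifier loci; or (c)
    ``leak_rate`` noise fires. An accession missing a genotype at any causal
    locus gets a missing phenotype.
    """
    rng = _rng(config.seed, "phenotype")
    maj = G.dosage[:, G.marker_index(*config.major_locus)]
    mods = [G.dosage[:, G.marker_index(c, p)] for c, p in config.modifier_loci]
    n = G.n_accessions

    loss_hom = maj == 2.0
    both_mod = (mods[0] == 2.0) & (mods[1] == 2.0)
    u_pen = rng.random(n)
    u_leak = rng.random(n)
    colorless = np.where(
        loss_hom,
        (u_pen < config.penetrance_major).astype(float),
        (both_mod | (u_leak < config.leak_rate)).astype(float),
    )
    missing = np.isnan(maj) | np.isnan(mods[0]) | np.isnan(mods[1])
    colorless[missing] = np.nan
    return pd.DataFrame({"accession_id": G.accession_ids, "trait": colorless})


def simulate_origins(G: GenotypeMatrix, config: SyntheticConfig) -> pd.DataFrame:
    """Geographic origins with corr(PC1, latitude) ~ ``geo_effect``.

    Latitude is ``geo_effect * z1 + sqrt(1-geo_effect^2) * noise`` (z1 the
    standardised genotype PC1) rescaled to a plausible latitude range; region
    labels are seven equal-count latitude bands, south to north:
    DR, WCR, ECR, CDZ, EMR, WMR, NMR. With ``geo_effect = 1`` the noise term
    vanishes and the correlation is exactly 1.
    """
    if G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    rng = _rng(config.seed, "origins")
    from .popstructure import pca

    res = pca(G, n_components=2)
    z = res.scores[:, :2]
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) > 0, z.std(axis=0), 1.0)

    def blend(effect, zcol):
        eps = rng.standard_normal(G.n_accessions)
        if abs(effect) >= 1.0:
            return np.sign(effect) * zcol
        return effect * zcol + np.sqrt(1 - effect**2) * eps

    lat = 20.0 + 4.0 * blend(config.geo_effect, z[:, 0])
    lon = 96.0 + 1.5 * blend(config.geo_effect_lon, z[:, 1])
    bands = pd.qcut(lat, q=len(REGION_LABELS), labels=REGION_LABELS, duplicates="drop")
    return pd.DataFrame(
        {
            "accession_id": G.accession_ids,
            "latitude": lat,
            "longitude": lon,
            "region": bands.astype(str),
        }
    )


def _format_gt(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[float(d)]


def write_fixture(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    origins: pd.DataFrame,
    out_dir: str,
    overwrite: bool = False,
    chrom_length_bp: int | None = None,
) -> dict:
    """Write the panel as VCF v4.2 + phenotype TSV + origin TSV.

    Refuses to overwrite existing files unless ``overwrite=True``; errors on
    an empty marker set before touching the filesystem. Returns the three
    paths. Round-trips losslessly through :func:`paddygwas.variants.read_vcf`.
    """
    if G.n_markers == 0:
        raise ValueError("refusing to write a fixture with no markers")
    if set(pheno["accession_id"]) != set(G.accession_ids) or set(
        origins["accession_id"]
    ) != set(G.accession_ids):
        raise ValueError("accession sets inconsistent across tables")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "pheno": os.path.join(out_dir, "phenotype.tsv"),
        "origins": os.path.join(out_dir, "origins.tsv"),
    }
    if not overwrite:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; pass overwrite=True")

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=paddygwas-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.chromosomes:
            cmax = G.markers.loc[G.markers["chrom"] == chrom, "pos"].max()
            length = chrom_length_bp if chrom_length_bp else int(cmax)
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        for j, row in enumerate(G.markers.itertuples(index=False)):
            gts = "\t".join(_format_gt(d) for d in G.dosage[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.chrom}_{row.pos}\t{row.ref}\t"
                f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    with open(paths["pheno"], "w") as fh:
        fh.write("# trait coding: colorless = 1, colored = 0\n")
        fh.write("accession_id\ttrait\n")
        for r in pheno.itertuples(index=False):
            v = "NA" if pd.isna(r.trait) else str(int(r.trait))
            fh.write(f"{r.accession_id}\t{v}\n")

    origins.to_csv(paths["origins"], sep="\t", index=False, float_format="%.6f")
    return paths


def read_phenotype(path: str) -> pd.DataFrame:
    """Read a phenotype TSV (accession_id, trait; '#' comment lines allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    df.columns = ["accession_id", "trait"]
    return df


def read_origins(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
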