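# Methods

This note documents the statistical models, the synthetic-panel generator,
numerical choices, and the limits of what the test suite demonstrates.

## Data model and marker post-filters

Genotypes are alt-allele dosages in {0, 1, 2} with missing calls as NaN,
read from VCF v4.2 (biallelic SNP records only; multi-allelic and indel
records are skipped with a logged count). Because the panel is fully
inbred, every heterozygous call is treated as genotyping noise and set to
missing before any analysis (`mask_heterozygotes`). Marker filters follow
the wording they were defined with: MAF strictly greater than the cutoff
(default 5%), missing rate less than or equal to the cap (default 20% for
association, 10% for structure analyses). Window pruning keeps one marker
per non-overlapping 20-kb bin anchored at position 0 (0-based, half-open);
within a bin the marker with the lowest missing rate wins, ties broken by
lowest position. Both conventions are deterministic choices where the
procedure definition is silent; "first marker per bin" is available as an
alternative policy.

## Population structure

PCA mean-imputes missing dosages per marker and centres columns
(variance scaling is available but off by default — inbred dosage data are
already on a common scale, and unscaled PCA keeps eigenvalue shares
interpretable as dosage variance). Distances for the neighbor-joining tree
are Euclidean over the same mean-imputed matrix, so PCA and the tree see
identical data; markers are subsampled without replacement (default 1,422)
to reduce redundancy. NJ is the classic Saitou–Nei agglomeration
(scikit-bio). Bootstrap support resamples marker columns with replacement,
rebuilds distance + tree, and counts how often each original bipartition
reappears; counts are reproducible bit-for-bit given the seed. Varietal
groups are obtained by deleting the k−1 longest internal edges (ties broken
by the sorted leaf set under the edge) — a deterministic, parameter-light
convention for cutting an unrooted tree where no published rule exists.
Geographic enrichment uses contingency-margin expected counts
(group total × region total / grand total); each group is assigned the
region with the largest observed/expected ratio, ties resolved by larger
observed count then lexicographic label.

## LD decay

500,000 same-chromosome marker pairs within 10 Mb are drawn uniformly
without replacement from the implicit pair space (rejection sampling over a
flat pair index; the pair set is never materialised). Sampling is
genome-wide and the fits are per-chromosome; the genome-wide d_LD50 is the
arithmetic mean of per-chromosome values. r² is the squared Pearson
correlation over pairwise-complete accessions — for homozygous lines this
equals haplotype r², so no EM phasing is needed; pairs with fewer than two
informative accessions or a monomorphic vector are dropped and counted.

The decay model E[r²] = (r²_high − r²_low)/(1 + d·r_d) + r²_low is fitted
by bounded nonlinear least squares in the parametrisation
(Δ = r²_high − r²_low, r²_low, r_d), which enforces
0 ≤ r²_low ≤ r²_high ≤ 1 and r_d > 0 with simple box bounds.
Initialisation: r²_high from the mean r² of the closest 1% of distances,
r²_low from the farthest 1%, r_d = 1/median(d); up to five jittered
restarts on solver failure; tolerances 1e-15 with Jacobian-based parameter
scaling, which recovers noise-free parameters to ≤1e-6 relative error. A
fit with Δ below 1e-9 is flagged unidentifiable (flat curve; r_d carries no
information). d_LD50 is computed as 1/r_d exactly, and the midpoint
identity — the curve at 1/r_d equals (r²_high + r²_low)/2 — is asserted at
machine precision on every call.

## Mixed-model association

The kinship matrix is K = ZZ'/m over standardised dosages
z = (x − 2p)/√(2p(1−p)), mean-imputed, monomorphic markers skipped. No
principal components enter the fixed effects by default: the intended
panel has no subpopulation structure, and the kinship random effect
carries the remaining relatedness.

*Quantitative response* (including the Gaussian model applied to a 0/1
coding as the conditional-scan fallback): y = Xβ + u + e, u ~ N(0, τK),
e ~ N(0, σ²I). REML profiles σ² out and maximises over λ = τ/σ² via the
eigendecomposition of K — a coarse log-grid (e^-10…e^10) followed by
bounded Brent refinement, with an explicit λ→0 boundary check.

*Binary response*: logistic linear mixed model fitted by penalized
quasi-likelihood. Each outer iteration forms the working response
z = η + (y − μ)/(μ(1−μ)) and working covariance Σ = τK + W⁻¹
(W = diag(μ(1−μ)), dispersion fixed at 1), re-estimates τ by working REML
(grid + Brent on log τ), and updates η = Xβ̂ + û. Convergence is max |Δη|
< 1e-6 within 100 iterations; non-convergence raises. At the PQL optimum
X'(y − μ̂) = 0 holds exactly, which makes the score test below invariant to
affine recoding of dosages.

*Score tests*: variance components stay at their null estimates (one null
fit per scan — the fast mixed-model GWAS strategy; exact per-marker
refitting is deliberately not the default). For marker g,
T = g'r with r the GLS residual V⁻¹(y − Xβ̂) (quantitative) or y − μ̂
(binary), Var(T) = g'Pg with P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹ (Σ in the
binary case), and T²/Var(T) ~ χ²₁. Pinning τ = 0 reduces the binary test
exactly to the classic logistic-regression score test, which is the oracle
the tests check against. Missing dosages are mean-imputed per marker so n
is constant across markers; zero-variance markers get a missing p.
Benjamini–Hochberg q-values are computed jointly over all tested markers;
the FDR-α threshold line is the −log10(p) of the largest p with q ≤ α,
or max observed + 1 when nothing is rejected (so no marker sits above it).

Conditional scans append the named marker dosages (mean-imputed) to the
fixed effects and exclude those markers from the scan; a constant covariate
is dropped by the collinearity screen, an all-missing one raises. The
binary conditional model can show genome-wide p-value inflation — the
near-deterministic residual amplifies chance correlations — which is why
the Gaussian-on-0/1 fallback is exposed and used by default for
conditional rescans.

## QTL calling

A region requires, within peak ± window (the genome-wide d_LD50 by
default), at least one marker at/above the significant line and at least
two markers at/above the suggestive line, the peak included — "multiple
suggestive markers" is read as "the peak is not alone", which is the
minimal reading that rejects isolated spikes. Claiming is greedy and
peak-first: the strongest unclaimed significant marker founds a candidate
window; all in-window markers are claimed whether or not the candidate is
accepted, so overlapping candidates merge into the stronger peak's region.
Ties in peak score break to the lower position. Regions are named
q<TRAIT><chrom>.<ordinal> in positional order per chromosome. Peak
correlations are complete-case Pearson correlations between peak dosage
vectors (diagonal exactly 1 for a polymorphic peak); local LD matrices use
the same r² estimator as the decay scan. Gene lookup intersects GFF3 gene
spans (1-based inclusive) with the window and reports distance from the
peak (0 inside the gene).

## Synthetic panel generator

The generator emulates a panel of ~250 fully inbred accessions drawn from
one unstructured gene pool, with marker MAF ≥ 5%, low missingness,
intra-chromosomal LD decaying with distance, a weak genotype–latitude
correlation, and a binary trait controlled by one major loss-of-function
locus plus two complementary modifiers.

*Genotypes.* Each accession's chromosome is a hidden-Markov mosaic of
founder haplotypes: between adjacent markers the copied founder switches
with probability 1 − exp(−switch_rate · gap). The founder pool itself
needs haplotype structure: with independent founder alleles, panel r²
cannot exceed ≈ 1/n_founders, because the allele partitions of the founder
set decorrelate between markers. The pool is therefore built from nested
partitions: ancestry segments (boundary rate founder_switch_rate, default
switch_rate/2) each fix a random founder ordering, and every marker's
alt-carrier set is a random-length prefix of that ordering. Carrier sets
of nearby markers are nested (D′ = 1 blocks), giving a high short-range r²
asymptote that decays to background across segment and copying switches.
Dosages are homozygous {0, 2} by construction; heterozygous calls
(default 1%) and missing calls (default 5%) are injected afterwards to
exercise downstream masking and filters. Markers whose realised panel MAF
falls below maf_min are dropped, and an oversampled candidate set (factor
1.5) is thinned back to the requested marker count.

*Causal loci.* The major locus and the two modifiers are forced to exist
as markers; their alt frequencies are pinned (loss allele 161/250 ≈ 0.64;
modifiers 0.26 each, so the double-homozygote rate among functional
carriers is ≈ 0.065) by fixing the prefix length while keeping the
segment's founder ordering, so the forced column keeps LD with its
neighbours. Causal columns are exempt from the MAF drop and from missing
and het injection so every accession has a defined causal genotype; an
accession missing a causal genotype (possible with user-modified matrices)
gets a missing phenotype.

*Phenotype.* Colorless (coded 1) iff loss-homozygous at the major locus
(probability penetrance_major, default 159/161 ≈ 0.988), or functional at
the major locus but alt-homozygous at both modifiers, or leak_rate noise
(default 0). The two exception channels let either hypothesis about
rare phenotype exceptions — complementary epistasis or scoring noise — be
simulated.

*Origins.* Latitude is geo_effect · z₁ + √(1 − geo_effect²) · ε with z₁
the standardised genotype PC1 (default geo_effect 0.39; with geo_effect=1
the correlation is exactly ±1), affinely mapped to a plausible range;
longitude likewise from PC2 (default 0.22). Regions are seven equal-count
latitude bands labelled south→north DR, WCR, ECR, CDZ, EMR, WMR, NMR — a
fixture convention only.

*Seeds.* One master seed; per-stage streams are derived with fixed spawn
keys so genotypes, phenotype and origins can be regenerated independently.
Identical (config, seed) gives byte-identical fixture files.

*Default scale.* 250 accessions × 12 chromosomes × 30 Mb × 5,000 markers,
n_founders = 20. switch_rate defaults to 1.25e-6/bp, calibrated once so the
default panel's genome-wide d_LD50 is ≈ 1e5 bp — the LD scale of the
panel the generator emulates. The mapping switch_rate → r_d is approximate
and always estimated empirically from the generated data, never assumed.

*What the generator does not emulate:* sequencing reads, genotype
likelihoods and depth-dependent error, subpopulation admixture,
quantitative traits, allele-frequency spectra of real mutation–drift
equilibria, and gene conversion. Tests passing on this generator therefore
demonstrate correctness of the statistical machinery under an idealised
inbred-panel model, not robustness to real-data artefacts such as
batch-structured missingness or reference bias.

## Numerical and degenerate-input conventions

* Mean imputation is the single convention for missing dosages in PCA,
  distances, GRM and score tests, so every stage sees the same matrix;
  complete-case computation is used only where a pairwise statistic
  demands it (pairwise r², peak correlations).
* All-missing markers are flagged (stats), rejected (PCA) or excluded
  (filters); constant phenotypes, empty marker sets, unsorted VCFs,
  non-symmetric distance matrices and chromosome-name mismatches raise
  with specific messages.
* BH q-values ignore missing p-values (they do not count toward m).
* Scan-threshold and QTL-window comparisons use ≥ on −log10(p), so a
  marker exactly on a line counts as passing it.
* Problem sizes in the test suite are chosen per test: toy matrices for
  oracle equivalences, a shared 3-chromosome panel for module tests, the
  full default panel (20 seeded replicates) for planted-locus recovery,
  and 500,000 model-generated pairs for the noisy LD-recovery check.

## Known limitations

* PQL is a first-order approximation; for rare binary traits or strong
  polygenic effects its τ is biased downward (the usual PQL caveat). The
  score test inherits the approximation.
* The Gaussian-on-0/1 conditional fallback is, strictly, a misspecified
  model; it is provided because the logistic conditional scan can inflate
  p-values genome-wide on near-deterministic traits.
* The greedy QTL rule can fragment one long causal haplotype block into a
  chain of window-sized regions when the block is much longer than
  d_LD50; the regions are correct under the stated rule, but downstream
  interpretation should treat adjacent regions with highly correlated
  peaks as one signal (the peak-correlation matrix makes this visible).
* NJ bootstrap support is reported as raw replicate counts, with no
  support threshold enforced for group reporting.
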