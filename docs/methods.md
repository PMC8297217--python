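# Methods

## The problem

When two closely related cell populations — the motivating case is the two
midbrain dopamine neuron populations, substantia nigra pars compacta (SNc)
and ventral tegmental area (VTA), profiled by laser-capture
microdissection RNA-seq — are compared across a cohort of human subjects,
the list of differentially expressed genes (DEGs) depends strongly on
*which* subjects happen to be in the cohort.  Inter-individual variability
makes small-cohort marker lists irreproducible.  `stableboot` implements a
resampling answer: repeatedly draw subject subsets **without
replacement**, run a fresh two-group differential-expression analysis on
each draw, and keep only the genes detected in a large fraction of all
draws ("stable genes").  The per-size saturation of newly discovered genes
additionally estimates the smallest cohort at which marker discovery
stops depending on subject selection.

## The bootstrap procedure

Given a paired cohort of `N` subjects (each contributing one sample per
group) and a ladder of subset sizes `i ∈ {3, …, N−1}`:

1. For each size `i`, draw `j` random subsets of `i` subjects, uniformly
   and without replacement within a draw (`j = 1000` by default).  Subsets
   may repeat across draws — unavoidable, since e.g. C(12, 3) = 220 < 1000;
   the number of distinct subsets drawn is logged in the run manifest.
2. Each draw's `2i` samples are tested for differential expression at
   BH-adjusted p < α (default 0.05).
3. Every detected gene increments a counter keyed by (gene, size,
   direction of fold-change).
4. **Stable genes** are genes whose summed detection count strictly
   exceeds `n_sizes × n_repeats × ratio`.  A gene crossing the threshold
   in *both* directions cannot be a marker of either population; it is
   excluded and flagged as direction-unstable.

Randomness uses a single master seed; the draw at (size `s`, repeat `r`)
comes from an independent child stream
`SeedSequence(seed, spawn_key=(s, r))`, so results for one size do not
depend on which other sizes were run, and the entire pipeline is
bit-reproducible for a fixed seed.

### Thresholds

Two cutoffs coexist in the original human study: the per-size cutoff is
30% of the draws at one size (300 of 1,000), while the overall cutoff
applied for the headline stable-gene lists was 3,000 of the 9,000 total
comparisons — one third, not 30%.  `BootstrapConfig` therefore carries
`ratio` (per-size; also the default overall fraction) and an optional
`overall_ratio`; `human_study_config()` reproduces the published
convention (`ratio=0.30`, `overall_ratio=1/3`).  Thresholds are strict
(`>`, never `≥`).

The `ratio` itself is a declared analysis choice.  `calibrate_ratio`
supports it empirically: for each candidate ratio it reports the stable
set size and the percentage of stable genes contained in the top 10%,
20%, … of the full-cohort DEG list ranked by adjusted p.  No ratio is
chosen automatically.

### Saturation and minimal cohort size

For each subset size the union of genes detected in at least one draw is
recorded; processed in ascending size order this yields the cumulative
count of distinct DEGs and the *novel* genes first seen at each size.
`estimate_min_sample_size` returns the smallest size from which every
larger size contributes at most `max(tol_abs, tol_frac × cumulative)`
novel genes (defaults `tol_abs = 5`, `tol_frac = 0.01`).  This rule is an
explicit operationalization of the visual judgement "few new genes appear
beyond this size"; both knobs are exposed because the judgement is
inherently a convention.  "Not reached" is a value, not an error.

### Unpaired designs

For unpaired data (e.g. single cells), draws select `i` samples per group
independently, and `balance_groups` optionally down-samples the larger
group once, before the loop, to equalize group sizes (the convention of
the mouse single-cell reanalysis: 73 cells per population).  Re-balancing
per draw is deliberately not the default.

## The reference DE engine

The engine follows the standard negative-binomial count model
(variance = μ + α μ²):

* **Size factors** — median-of-ratios over reference genes (rows positive
  in every sample), rescaled to geometric mean exactly 1.  The rescaling
  fixes the arbitrary global constant so that factor *ratios* are exactly
  scale-equivariant; it does not affect the group contrast.  A
  `pseudo_reference` option handles sparse matrices with no all-positive
  row.
* **Dispersion** — per-gene method of moments on size-factor normalized
  counts: `α̂ = max(0, (s² − μ̄) / μ̄²)`, where `s²` is the pooled
  within-group variance (residual around group means, matching the
  conditional NB model) and `μ̄` the overall normalized mean; clamped to
  `[1e-8, 10]`.  A per-gene MLE (profile likelihood at fixed group means)
  is available as `method="mle"`.
* **Dispersion moderation** — raw gene-wise estimates are far too noisy
  at the small subset sizes the ladder requires: with 3 subjects per
  group (4 residual df) a sizeable fraction of null genes draw a
  near-zero dispersion estimate, get near-Poisson standard errors, and
  the Wald test produces dozens of false discoveries per draw.  The
  engine therefore squeezes gene-wise estimates toward a common
  dispersion (10%-trimmed mean over genes with normalized mean ≥ 1) with
  a prior worth `prior_df = 10` residual degrees of freedom — the classic
  moderated-dispersion weighting.  Measured effect on all-null data:
  the raw p < 0.05 fraction moves from ~0.07–0.08 (with heavy-tailed
  per-draw false-discovery cascades at small sizes) to 0.05–0.06, and
  null bootstrap runs produce empty stable sets.  The squeeze can be
  disabled (`shrink_dispersion=False`).
* **Wald test** — per-gene NB GLM with log link, design
  `intercept + group indicator`, size factors as offsets, fitted by IRLS
  vectorized across genes (closed-form 2×2 weighted least squares per
  iteration; convergence 1e-10, max 60 iterations, coefficients bounded
  at ±50 on the natural-log scale to contain complete-separation genes).
  The statistic is β̂/SE(β̂) against a standard normal, two-sided;
  `log2fc = β̂ / ln 2`.
* **Multiple testing** — Benjamini–Hochberg step-up over non-missing
  p-values; all-zero genes are dropped before testing, and a missing
  adjusted p counts as not differentially expressed.

Deliberately **not** implemented (full-DESeq2 fidelity is out of scope by
design): dispersion trend fitting, LFC priors/shrinkage, Cook's outlier
handling, independent filtering.  The bootstrap wrapper is
engine-agnostic: `engine="pydeseq2"` (alias `"external"`) plugs in the
pydeseq2 implementation of DESeq2 through the same interface for
fidelity runs, and is used in the test suite as an independent
cross-check of the reference engine on strong planted effects.  Exact
replication of the original human DEG lists is not promised: those
depend on a 2017-era DESeq2 version's defaults.

Genes with complete separation (one group all zero) get very large
fold-change estimates with very large standard errors and hence
non-significant Wald p — the Hauck–Donner effect, shared by unpenalized
NB GLMs generally.  This costs sensitivity only for strongly DE genes
with near-zero baseline expression.

## Count-level processing and QC

`read_counts`/`write_counts` handle TSV/CSV (genes in rows) and
MatrixMarket with sidecar name files.  RPKM is
`counts / (length_kb × mapped_millions)` with the per-sample denominator
taken from metadata total mapped reads (the convention of read-counting
tools, where the library total exceeds the in-matrix sum) or column sums
as a fallback.  Gene lengths are caller-supplied (union-exon lengths
expected); no annotation is downloaded.

Sample QC mirrors the LCM-seq screening conventions: minimum total reads
(default 1e6), minimum genes detected at RPKM > 1 (default 4,600), and a
nearest-sample Pearson correlation (computed on log2(RPKM+1); the log
transform stabilizes the statistic) above 0.7.  Replicates of the same
(subject, group) are averaged arithmetically and rounded **half-up** to
integers so the count-model assumptions downstream still hold; the paper
trail only says "averaged", so the rounding rule is recorded in the
dataset provenance.  Marker purity checks each sample for expression of
positive identity markers (defaults: the midbrain dopamine neuron panel
EN1, EN2, FOXA2, LMX1B, PITX3, NR4A2, TH, SLC6A3, NEFH) and absence of
contamination markers (MFGE8, CX3CR1, GPR17); all lists and thresholds
are editable.

## Panel validation

`hierarchical_classify` clusters samples on the panel genes only:
log-scale expression, per-gene z-scored by default (making the result
invariant to per-gene affine rescaling), Euclidean distance, Ward linkage
(the ward.D2 convention), tree cut at k = 2.  Clusters are matched to
true group labels by maximum-agreement (Hungarian) assignment and
misclassified samples counted per group.  Whether the original heatmaps
were clustered on z-scored or raw log expression is not documented;
z-scoring is the default and both are supported.  `pca_project` returns
PC1/PC2 coordinates of gene-centered (unscaled) expression with a fixed
sign convention (largest-magnitude loading positive) for
reproducibility.  `evaluate_panel_transfer` applies a panel called on one
cohort to a new labeled cohort, reporting the fraction of panel genes
found and per-group misclassification.

## The synthetic cohort generator

Counts for gene g, subject s, group k are NB with mean

    L[s,k] · q[g] · 2^(u[s] + b[g]·1[k = group2])

* `q` — baseline relative expression, log-normal with ln-scale SD 1.5
  (normalized to sum 1).  At the default library size this puts the
  median gene at ~60–70 counts with a broad dynamic range and <1% of
  genes below one expected count, qualitatively mimicking the detected-
  gene ranges of the real assay without calibrating to it.
* `u` — subject random effect, Normal(0, 0.3) in log2 units, shared by
  both of a subject's samples.  This is the minimal mechanism by which
  the identity of the drawn subjects changes DEG lists — the phenomenon
  the bootstrap addresses.  The real inter-subject variance is unknown;
  0.3 is a declared free parameter.
* `b` — planted log2 fold-change: 2% of genes, |b| uniform in [1.5, 4],
  directions balanced; zero elsewhere.  Ground truth is returned with
  the counts.
* `L` — per-sample library size, log-normal with median 1e6 and ln-scale
  SD 0.25.
* NB dispersion α = 0.2 (Poisson at α = 0).

Defaults describe a 12-subject paired cohort with 5,000 genes
(`default_paper_like_design()`).  The generator does **not** model
gene-length/GC bias, single-cell dropout, read-level noise, or correlated
co-expression modules; passing tests therefore demonstrate the
statistical behaviour of the procedure under its own model assumptions,
not performance on any real tissue dataset.  `simulate_dataset` can
re-simulate a fresh cohort against an existing ground-truth table, which
is how panel-transfer experiments generate independent validation
cohorts with the same planted markers.

## Problem sizes used in the shipped analyses

The acceptance analysis (`scripts/acceptance.py`) uses 200 bootstrap
repeats per size on the default 5,000-gene design for the recovery run
and 100 repeats at sizes 3–7 on 2,000-gene null cohorts (20 of them) for
calibration — scales chosen so a complete from-scratch run finishes in a
few minutes on one core while keeping the binomial noise on the reported
fractions well inside the asserted bands.  Typical results at these
scales: stable-gene recall of planted markers ≈ 0.98, false-discovery
proportion ≈ 0.04, null p < 0.05 fraction ≈ 0.06, saturation at 8
subjects, and zero misclassified samples when fresh cohorts are clustered
on the called panel.

## Known limitations

* The reference engine's calibration relies on the moderated dispersion;
  with `shrink_dispersion=False` it is anticonservative below ~6 samples
  per group.
* Stable-gene frequencies are counted per direction; a gene oscillating
  in sign across draws is flagged rather than ranked, which differs from
  analyses that pool absolute detection.
* Only two-group designs, no covariates, no multi-factor models.
* The saturation rule is a surrogate for a visual judgement; its
  defaults (5 genes or 1% of cumulative) are conventions, and different
  tolerances can move the estimated minimal cohort size by ±1.
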