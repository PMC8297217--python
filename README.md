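# stableboot

Bootstrap stability selection of differential-expression markers between
two closely related cell populations.

## Why

Marker-gene lists obtained by comparing two similar cell populations
across a cohort of subjects (the motivating case: human substantia nigra
pars compacta vs. ventral tegmental area dopamine neurons profiled by
LCM-seq) are notoriously unstable — swap a few subjects and the DEG list
changes.  `stableboot` quantifies and exploits that instability:

* draw many random subject subsets **without replacement**, at an
  increasing ladder of subset sizes `i = 3, 4, …, N−1`;
* run a fresh two-group negative-binomial Wald test (median-of-ratios
  normalization, moderated gene-wise dispersion, BH adjustment at
  adjusted p < 0.05) on every draw;
* call **stable genes**: genes whose detection count across all draws
  strictly exceeds `n_sizes × n_repeats × ratio` (per-size cutoff
  `n_repeats × ratio`; ratio 0.30 by default, with the original study's
  one-third overall convention available as `human_study_config()`);
* read the **minimal cohort size** off the saturation curve — the
  smallest subset size beyond which almost no previously unseen DEGs
  appear;
* validate a called panel by Ward hierarchical clustering / PCA of
  samples restricted to the panel genes, including transfer to a new
  labeled cohort with misclassification counting.

A synthetic-data module generates paired two-group NB cohorts with
subject-level random effects and planted fold-changes (with ground
truth), so the whole pipeline is testable without any download.

## Worked example

```bash
# 1. simulate a 12-subject paired cohort, 5000 genes, 2% planted DE
stableboot simulate --subjects 12 --genes 5000 --frac-de 0.02 \
    --seed 11 --out sim/

# 2. bootstrap stability selection over subset sizes 3..11
stableboot bootstrap --counts sim/counts.tsv --meta sim/metadata.tsv \
    --sizes 3:11 --repeats 200 --ratio 0.30 --seed 11 --out run/
```

which prints

```
simulated 5000 genes x 24 samples -> sim
100 stable genes (cutoff > 540 of 1800) -> run
```

i.e. 9 subset sizes × 200 repeats = 1,800 DE comparisons were run, the
stability cutoff was 540 detections (30% of 1,800), and 100 genes
cleared it.  Checking against the simulated ground truth
(`sim/truth.tsv`: 100 planted DE genes), 99 of the 100 stable genes are
planted markers.  `run/saturation.tsv` holds the saturation curve:

```
size  mean_degs_per_draw  novel  cumulative_distinct
3     90.880              914    914
...
8     109.465             7      1324
9     109.255             1      1325
10    109.650             0      1325
11    109.590             0      1325
```

and the manifest reports `"min_saturating_size": 8` — from 8 subjects on,
essentially no new genes appear, so 8 subjects suffice for stable marker
discovery in this cohort.  Validate the called panel on the samples:

```bash
cut -f1 run/stable_genes.tsv | tail -n +2 > panel.txt
stableboot classify --counts sim/counts.tsv --meta sim/metadata.tsv \
    --panel panel.txt --out cls/
# -> misclassified: 0
```

The same operations are available as a library
(`simulate_dataset`, `bootstrap_frequencies`, `call_stable_genes`,
`saturation_curve`, `estimate_min_sample_size`,
`hierarchical_classify`, …); every CLI run writes a `manifest.json` with
the merged configuration, master seed, seeding policy and input digests,
sufficient to re-run bit-identically.

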