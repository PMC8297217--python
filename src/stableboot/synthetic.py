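"""Synthetic paired two-group NB count data with planted DE genes.

The generator emulates the study design the bootstrap targets: a cohort of
subjects each contributing one sample per group (e.g., two neighbouring
neuron populations dissected from the same brain), with

* negative-binomial counts (variance = mu + alpha mu^2),
* a subject-level random effect shared by both of a subject's samples
  (inter-individual variability, the reason subject subsets disagree),
* log-normal library sizes, and
* a configurable fraction of genes with planted log2 fold-changes in
  balanced directions.

Ground truth (which genes are DE, their true fold-changes) is returned
alongside the counts so that recall and false-discovery proportion of the
stability selection can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .io_qc import CountDataset


@dataclass(frozen=True)
class SyntheticDesign:
    """Generative parameters of a paired two-group count dataset.

    Defaults describe a human-cohort-style design: 12 paired subjects,
    5,000 genes, 2% planted DE at |log2fc| uniform in [1.5, 4], NB
    dispersion 0.2, subject effect SD 0.3 (log2 scale) and log-normal
    library sizes with median one million reads.
    """

    n_subjects: int = 12
    n_genes: int = 5000
    frac_de: float = 0.02
    log2fc_low: float = 1.5
    log2fc_high: float = 4.0
    dispersion: float = 0.2            # scalar NB alpha; 0 -> Poisson
    subject_effect_sd: float = 0.3     # SD of subject effect, log2 units
    baseline_log_sd: float = 1.5       # SD of ln(baseline expression)
    library_size_median: float = 1e6
    library_size_sigma: float = 0.25   # SD of ln(library size)
    paired: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not (0 <= self.frac_de <= 1):
            raise ValueError("frac_de must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size_median <= 0 or self.library_size_sigma < 0:
            raise ValueError("library size parameters must be positive")
        if self.subject_effect_sd < 0:
            raise ValueError("subject_effect_sd must be >= 0")
        n_de = int(round(self.frac_de * self.n_genes))
        if self.frac_de > 0 and n_de < 1:
            raise ValueError(
                "frac_de > 0 but frac_de * n_genes rounds to zero genes")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))

    def to_dict(self) -> dict:
        return asdict(self)


def default_paper_like_design(seed: int = 0) -> SyntheticDesign:
    """The default cohort design: 12 paired subjects, ladder 3..11 intended
    downstream."""
    return SyntheticDesign(seed=seed)


def _nb_sample(rng, mean, alpha):
    """NB draws with variance mu + alpha mu^2 (Poisson when alpha == 0)."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_dataset(design: SyntheticDesign,
                     ground_truth: Optional[pd.DataFrame] = None
                     ) -> tuple[CountDataset, pd.DataFrame]:
    """Simulate counts under the paired NB model with subject effects.

    For gene g, subject s, group k the count is NB with mean
    ``L[s,k] * q[g] * 2**(u[s] + b[g] * [k == group2])`` where ``u`` is the
    subject random effect, ``b`` the planted log2 fold-change, ``L`` the
    library size and ``q`` the baseline relative expression.

    Pass an existing ``ground_truth`` table to re-simulate a fresh cohort
    with the same planted genes and fold-changes (used for panel-transfer
    experiments); otherwise the truth is drawn from the design.

    Returns ``(dataset, truth)`` where ``truth`` has one row per gene with
    ``is_de``, ``true_log2fc`` and ``direction``.
    """
    rng = np.random.default_rng(design.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(design.n_genes)], name="gene")

    if ground_truth is None:
        b = np.zeros(design.n_genes)
        n_de = design.n_de
        if n_de:
            de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
            mags = rng.uniform(design.log2fc_low, design.log2fc_high,
                               size=n_de)
            signs = np.ones(n_de)
            signs[: n_de // 2] = -1.0   # balanced directions
            rng.shuffle(signs)
            b[de_idx] = mags * signs
        truth = pd.DataFrame({
            "is_de": b != 0,
            "true_log2fc": b,
            "direction": np.where(b > 0, "group2_enriched",
                                  np.where(b < 0, "group1_enriched", "")),
        }, index=genes)
    else:
        truth = ground_truth.copy()
        if len(truth) != design.n_genes:
            raise ValueError("ground_truth length does not match n_genes")
        truth.index = genes
        b = truth["true_log2fc"].to_numpy().astype(float)

    # baseline relative expression: broad log-normal dynamic range
    q = rng.lognormal(mean=0.0, sigma=design.baseline_log_sd,
                      size=design.n_genes)
    q = q / q.sum()

    n = design.n_subjects
    u = rng.normal(0.0, design.subject_effect_sd, size=n)  # log2 units
    groups = ("group1", "group2")
    cols = {}
    rows = []
    for k, grp in enumerate(groups):
        for s in range(n):
            lib = rng.lognormal(np.log(design.library_size_median),
                                design.library_size_sigma)
            if design.paired:
                subj_effect = u[s]
                subject = f"subj{s + 1:02d}"
            else:
                # unpaired: every sample is an independent unit (cell)
                subj_effect = rng.normal(0.0, design.subject_effect_sd)
                subject = f"{grp}_unit{s + 1:03d}"
            mean = lib * q * np.exp2(subj_effect + b * (k == 1))
            sid = f"S{s + 1:02d}_{grp}"
            cols[sid] = _nb_sample(rng, mean, design.dispersion)
            rows.append({"sample_id": sid, "subject_id": subject,
                         "group": grp})
    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(rows)
    meta["total_reads"] = [int(counts[s].sum()) for s in meta["sample_id"]]
    dataset = CountDataset(counts, meta,
                           provenance={"generator": "stableboot.synthetic",
                                       "design": design.to_dict()})
    return dataset, truth
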