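"""Bootstrap-without-replacement stability selection of DE genes.

The procedure: for each subset size ``i`` in an increasing ladder, draw
``n_repeats`` random subject subsets without replacement (within a draw),
run a fresh two-group DE analysis on each draw, and record how often each
gene is called DE in each direction.  Genes whose total detection count
across every draw strictly exceeds ``n_sizes * n_repeats * ratio`` are
"stable genes" — markers robust to which subjects happened to be sampled.
The per-size union of detected genes yields a saturation curve whose
novel-gene increments estimate the minimal cohort size at which DE
detection saturates.

Subsets may repeat across repeats (for 12 subjects and i = 3 there are only
C(12,3) = 220 distinct subsets); the number of distinct subsets actually
drawn is logged.  Randomness uses one master seed spawning an independent
child stream per (size, repeat), so the draw at (s, r) does not depend on
which other sizes run.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_qc import CountDataset
from . import de as _de

DEFAULT_SUBSET_SIZES = tuple(range(3, 12))   # paired human-style ladder
MOUSE_STYLE_SIZES = tuple(range(20, 75, 5))  # unpaired single-cell ladder


@dataclass(frozen=True)
class BootstrapConfig:
    """Configuration of a bootstrap stability run.

    ``subset_sizes`` is the ladder of subjects (paired mode) or cells per
    group (unpaired mode) to draw; ``ratio`` is the stability threshold as
    a fraction of the total number of comparisons.
    """

    subset_sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES
    n_repeats: int = 1000
    alpha: float = 0.05
    ratio: float = 0.30
    overall_ratio: float | None = None
    paired: bool = True
    seed: int = 0
    engine: str = "reference"
    dispersion_method: str = "moments"
    pseudo_reference: bool = False

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.subset_sizes)
        object.__setattr__(self, "subset_sizes", sizes)
        if len(sizes) == 0:
            raise ValueError("subset_sizes must be non-empty")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("subset_sizes must be strictly increasing")
        if min(sizes) < 2:
            raise ValueError("subset sizes below 2 cannot support a DE test")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0 < self.ratio <= 1):
            raise ValueError("ratio must lie in (0, 1]")
        if self.overall_ratio is not None and not (0 < self.overall_ratio <= 1):
            raise ValueError("overall_ratio must lie in (0, 1] or be None")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    # -- threshold arithmetic ---------------------------------------------
    @property
    def planned_comparisons(self) -> int:
        """Total DE analyses: one per (size, repeat)."""
        return len(self.subset_sizes) * self.n_repeats

    @property
    def per_size_cutoff(self) -> float:
        """Detection-count cutoff within a single subset size."""
        return self.n_repeats * self.ratio

    @property
    def overall_cutoff(self) -> float:
        """Detection-count cutoff summed over all subset sizes.

        Uses ``overall_ratio`` when set, else ``ratio``.  The original
        human study applied a per-size cutoff of 30% (300 of 1,000) but an
        overall cutoff of one third (3,000 of 9,000); pass
        ``overall_ratio=1/3`` to reproduce that convention
        (:func:`human_study_config`).
        """
        r = self.ratio if self.overall_ratio is None else self.overall_ratio
        return self.planned_comparisons * r

    def validate_units(self, n_units: int) -> None:
        if max(self.subset_sizes) >= n_units:
            raise ValueError(
                f"largest subset size {max(self.subset_sizes)} must be "
                f"smaller than the number of available units ({n_units})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subset_sizes"] = list(self.subset_sizes)
        return d


def human_study_config(seed: int = 0, **overrides) -> BootstrapConfig:
    """The human-cohort convention: sizes 3..11, 1,000 repeats, per-size
    cutoff 30% (300 of 1,000) and overall cutoff one third (3,000 of
    9,000)."""
    kwargs = dict(subset_sizes=DEFAULT_SUBSET_SIZES, n_repeats=1000,
                  ratio=0.30, overall_ratio=1 / 3, seed=seed)
    kwargs.update(overrides)
    return BootstrapConfig(**kwargs)


def _rng_for(seed: int, size: int, repeat: int, attempt: int = 0):
    key = (int(size), int(repeat)) if attempt == 0 \
        else (int(size), int(repeat), int(attempt))
    return np.random.default_rng(np.random.SeedSequence(int(seed),
                                                        spawn_key=key))


# ---------------------------------------------------------------------------
# Drawing
# ---------------------------------------------------------------------------

def draw_subset(units, i: int, rng, paired: bool = True):
    """Draw ``i`` distinct units uniformly without replacement.

    Paired mode: ``units`` is a sequence of subject ids; the returned
    subjects contribute both of their samples downstream.  Unpaired mode:
    ``units`` is a mapping group -> sample ids and ``i`` samples are drawn
    independently per group; a dict is returned.
    """
    if paired:
        units = list(units)
        if i > len(units):
            raise ValueError(f"cannot draw {i} from {len(units)} units")
        idx = rng.choice(len(units), size=i, replace=False)
        return sorted(units[j] for j in idx)
    out = {}
    for grp in sorted(units):
        pool = list(units[grp])
        if i > len(pool):
            raise ValueError(f"cannot draw {i} from {len(pool)} units "
                             f"in group '{grp}'")
        idx = rng.choice(len(pool), size=i, replace=False)
        out[grp] = sorted(pool[j] for j in idx)
    return out


def balance_groups(dataset: CountDataset, rng) -> tuple[CountDataset, dict]:
    """Down-sample the larger of two groups, once, to equalize group sizes.

    Intended for unpaired designs before bootstrapping.  Returns the
    balanced dataset and an info dict recording which samples were kept and
    dropped; an already balanced dataset is returned unchanged with a
    notice.
    """
    groups = dataset.groups
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    by_group = {g: [s for s in dataset.sample_ids
                    if dataset.meta.loc[s, "group"] == g] for g in groups}
    n1, n2 = len(by_group[groups[0]]), len(by_group[groups[1]])
    if n1 == n2:
        return dataset, {"already_balanced": True, "dropped": []}
    large = groups[0] if n1 > n2 else groups[1]
    small_n = min(n1, n2)
    pool = by_group[large]
    keep_idx = sorted(rng.choice(len(pool), size=small_n, replace=False))
    kept_large = [pool[j] for j in keep_idx]
    kept = [s for s in dataset.sample_ids
            if dataset.meta.loc[s, "group"] != large or s in set(kept_large)]
    dropped = [s for s in dataset.sample_ids if s not in set(kept)]
    return dataset.subset_samples(kept), {
        "already_balanced": False,
        "downsampled_group": large,
        "kept": kept_large,
        "dropped": dropped,
    }


# ---------------------------------------------------------------------------
# Frequency accumulation
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Per-gene, per-size, per-direction detection counts over all draws.

    ``counts`` maps a direction label (``<group>_enriched``) to a
    genes x sizes integer DataFrame.  ``detected_any`` marks, per gene and
    size, whether the gene was called DE (either direction) in at least one
    draw of that size — the per-size distinct DEG sets behind the
    saturation curve.
    """

    genes: pd.Index
    sizes: tuple[int, ...]
    n_repeats: int
    group_order: tuple[str, str]
    counts: dict[str, pd.DataFrame]
    padj_sum: dict[str, pd.Series]
    detected_any: pd.DataFrame
    mean_degs_per_draw: pd.Series
    n_distinct_subsets: dict[int, int]
    config: BootstrapConfig

    @property
    def directions(self) -> tuple[str, str]:
        return (f"{self.group_order[0]}_enriched",
                f"{self.group_order[1]}_enriched")

    def totals(self, direction: str) -> pd.Series:
        return self.counts[direction].sum(axis=1)

    def _check(self) -> None:
        for d, df in self.counts.items():
            if (df.to_numpy() < 0).any() or (df.to_numpy() > self.n_repeats).any():
                raise AssertionError(
                    f"frequency cell outside [0, n_repeats] for {d}")
            tot = df.to_numpy().sum(axis=1)
            if (tot > self.n_repeats * len(self.sizes)).any():
                raise AssertionError("total frequency exceeds draw count")

    # -- persistence -------------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for d, df in self.counts.items():
            out = df.copy()
            out.insert(0, "gene", out.index)
            out.to_csv(outdir / f"frequency_{d}.tsv", sep="\t", index=False)
        pads = pd.DataFrame({f"padj_sum_{d}": s for d, s in self.padj_sum.items()})
        pads.insert(0, "gene", pads.index)
        pads.to_csv(outdir / "padj_sums.tsv", sep="\t", index=False)
        det = self.detected_any.astype(int).copy()
        det.insert(0, "gene", det.index)
        det.to_csv(outdir / "detected_any.tsv", sep="\t", index=False)
        meta = {
            "sizes": list(self.sizes),
            "n_repeats": self.n_repeats,
            "group_order": list(self.group_order),
            "mean_degs_per_draw": {str(k): float(v)
                                   for k, v in self.mean_degs_per_draw.items()},
            "n_distinct_subsets": {str(k): int(v)
                                   for k, v in self.n_distinct_subsets.items()},
            "config": self.config.to_dict(),
        }
        (outdir / "frequency_meta.json").write_text(
            json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, outdir) -> "FrequencyTable":
        outdir = Path(outdir)
        meta = json.loads((outdir / "frequency_meta.json").read_text())
        config = BootstrapConfig(**{k: (tuple(v) if k == "subset_sizes" else v)
                                    for k, v in meta["config"].items()})
        group_order = tuple(meta["group_order"])
        dirs = (f"{group_order[0]}_enriched", f"{group_order[1]}_enriched")
        counts = {}
        for d in dirs:
            df = pd.read_csv(outdir / f"frequency_{d}.tsv", sep="\t",
                             index_col="gene")
            df.columns = [int(c) for c in df.columns]
            counts[d] = df
        pads = pd.read_csv(outdir / "padj_sums.tsv", sep="\t", index_col="gene")
        padj_sum = {d: pads[f"padj_sum_{d}"] for d in dirs}
        det = pd.read_csv(outdir / "detected_any.tsv", sep="\t",
                          index_col="gene").astype(bool)
        det.columns = [int(c) for c in det.columns]
        genes = counts[dirs[0]].index
        return cls(
            genes=genes, sizes=tuple(meta["sizes"]),
            n_repeats=int(meta["n_repeats"]), group_order=group_order,
            counts=counts, padj_sum=padj_sum, detected_any=det,
            mean_degs_per_draw=pd.Series(
                {int(k): v for k, v in meta["mean_degs_per_draw"].items()}),
            n_distinct_subsets={int(k): v
                                for k, v in meta["n_distinct_subsets"].items()},
            config=config,
        )


def _paired_layout(dataset: CountDataset):
    """Column indices per subject (one sample per group) for paired draws."""
    groups = dataset.groups
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    cols = {s: i for i, s in enumerate(dataset.sample_ids)}
    layout = {}
    for subj, sub in dataset.meta.groupby("subject_id"):
        owned = {g: [cols[s] for s in sub.index[sub["group"] == g]]
                 for g in groups}
        if any(len(v) != 1 for v in owned.values()):
            raise ValueError(
                f"paired mode requires exactly one sample per group per "
                f"subject; subject '{subj}' owns "
                f"{ {g: len(v) for g, v in owned.items()} } "
                "(average replicates first)")
        layout[str(subj)] = (owned[groups[0]][0], owned[groups[1]][0])
    return groups, layout


def bootstrap_frequencies(dataset: CountDataset,
                          config: BootstrapConfig) -> FrequencyTable:
    """Run the full bootstrap loop and accumulate detection frequencies.

    For every (size, repeat) a subject subset is drawn, the DE engine run
    at ``config.alpha``, and each called DEG increments the counter of its
    fold-change direction.  An engine failure on a draw is retried once
    with a fresh subset from the same stream, then aborts with diagnostics.
    """
    groups = dataset.groups
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    x = dataset.counts.to_numpy()
    n_genes = x.shape[0]

    if config.paired:
        _, layout = _paired_layout(dataset)
        units = sorted(layout)
        config.validate_units(len(units))
    else:
        by_group = {g: [s for s in dataset.sample_ids
                        if dataset.meta.loc[s, "group"] == g] for g in groups}
        cols = {s: i for i, s in enumerate(dataset.sample_ids)}
        config.validate_units(min(len(v) for v in by_group.values()))

    engine_is_reference = config.engine == "reference"
    if not engine_is_reference:
        engine = _de.get_engine(config.engine)

    sizes = config.subset_sizes
    n_sizes = len(sizes)
    up = np.zeros((n_genes, n_sizes), dtype=np.int64)    # group2-enriched
    down = np.zeros((n_genes, n_sizes), dtype=np.int64)  # group1-enriched
    padj_up = np.zeros(n_genes)
    padj_down = np.zeros(n_genes)
    seen = np.zeros((n_genes, n_sizes), dtype=bool)
    degs_per_size = np.zeros(n_sizes, dtype=np.int64)
    distinct: dict[int, set] = {s: set() for s in sizes}

    for si, size in enumerate(sizes):
        for rep in range(config.n_repeats):
            rng = _rng_for(config.seed, size, rep)
            last_err = None
            for attempt in range(2):
                if config.paired:
                    chosen = draw_subset(units, size, rng, paired=True)
                    col_idx = [layout[s][0] for s in chosen] + \
                              [layout[s][1] for s in chosen]
                    ind = np.array([0] * size + [1] * size)
                    key = tuple(chosen)
                else:
                    chosen = draw_subset(by_group, size, rng, paired=False)
                    col_idx = [cols[s] for s in chosen[groups[0]]] + \
                              [cols[s] for s in chosen[groups[1]]]
                    ind = np.array([0] * size + [1] * size)
                    key = tuple(chosen[groups[0]]) + tuple(chosen[groups[1]])
                try:
                    if engine_is_reference:
                        lfc, _, padj = _de.reference_fit_arrays(
                            x[:, col_idx], ind,
                            dispersion_method=config.dispersion_method,
                            pseudo_reference=config.pseudo_reference)
                    else:
                        sub = dataset.subset_samples(
                            [dataset.sample_ids[c] for c in col_idx])
                        table = engine.run(sub, group_order=groups)
                        lfc = table["log2fc"].to_numpy()
                        padj = table["padj"].to_numpy()
                    last_err = None
                    break
                except Exception as exc:  # retried once, then fatal
                    last_err = exc
            if last_err is not None:
                raise RuntimeError(
                    f"DE engine failed twice at size={size} repeat={rep}: "
                    f"{last_err}") from last_err
            distinct[size].add(key)
            det = np.asarray(pd.notna(padj)) & (padj < config.alpha)
            gup = det & (lfc > 0)
            gdown = det & (lfc < 0)
            up[:, si] += gup
            down[:, si] += gdown
            padj_up[gup] += padj[gup]
            padj_down[gdown] += padj[gdown]
            seen[:, si] |= det
            degs_per_size[si] += int(det.sum())

    d1 = f"{groups[0]}_enriched"
    d2 = f"{groups[1]}_enriched"
    genes = dataset.gene_ids
    freq = FrequencyTable(
        genes=genes,
        sizes=sizes,
        n_repeats=config.n_repeats,
        group_order=(groups[0], groups[1]),
        counts={
            d1: pd.DataFrame(down, index=genes, columns=list(sizes)),
            d2: pd.DataFrame(up, index=genes, columns=list(sizes)),
        },
        padj_sum={
            d1: pd.Series(padj_down, index=genes),
            d2: pd.Series(padj_up, index=genes),
        },
        detected_any=pd.DataFrame(seen, index=genes, columns=list(sizes)),
        mean_degs_per_draw=pd.Series(degs_per_size / config.n_repeats,
                                     index=list(sizes)),
        n_distinct_subsets={s: len(v) for s, v in distinct.items()},
        config=config,
    )
    freq._check()
    return freq


# ---------------------------------------------------------------------------
# Stable-gene calling
# ---------------------------------------------------------------------------

@dataclass
class StableGeneReport:
    """Stable genes ranked by total detection frequency, split by direction."""

    table: pd.DataFrame                # gene, direction, total, per-size, rank
    direction_unstable: list[str]      # genes above cutoff in both directions
    per_size_cutoff: float
    overall_cutoff: float
    config: BootstrapConfig
    group_order: tuple[str, str]

    @property
    def stable_genes(self) -> list[str]:
        return list(self.table.index)

    def genes_for(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["direction"] == direction])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)


def call_stable_genes(freq: FrequencyTable,
                      config: BootstrapConfig | None = None) -> StableGeneReport:
    """Call stable genes: total per-direction detection count strictly above
    ``n_sizes * n_repeats * ratio``.

    A gene exceeding the cutoff in both directions cannot be a marker of
    either population and is excluded but flagged.  Ranking is by total
    frequency (descending), ties broken by smaller mean adjusted p over
    detecting draws, then by gene id.
    """
    config = config or freq.config
    r = config.ratio if config.overall_ratio is None else config.overall_ratio
    cutoff = len(freq.sizes) * freq.n_repeats * r
    d1, d2 = freq.directions
    tot = {d: freq.totals(d) for d in (d1, d2)}
    above = {d: tot[d] > cutoff for d in (d1, d2)}
    both = above[d1] & above[d2]
    unstable = sorted(freq.genes[both])

    rows = []
    for d in (d1, d2):
        sel = above[d] & ~both
        for gene in freq.genes[sel]:
            total = int(tot[d].loc[gene])
            mean_padj = freq.padj_sum[d].loc[gene] / total if total else np.nan
            row = {"gene": gene, "direction": d, "total_frequency": total,
                   "mean_padj": mean_padj}
            for s in freq.sizes:
                row[f"freq_{s}"] = int(freq.counts[d].loc[gene, s])
            rows.append(row)
    if rows:
        table = pd.DataFrame(rows).set_index("gene")
        table = table.sort_values(
            by=["direction", "total_frequency", "mean_padj"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        # deterministic tie-break on gene id within equal (total, mean_padj)
        table["_gid"] = table.index
        table = table.sort_values(
            by=["direction", "total_frequency", "mean_padj", "_gid"],
            ascending=[True, False, True, True], kind="mergesort")
        table = table.drop(columns="_gid")
        table["rank"] = table.groupby("direction").cumcount() + 1
    else:
        cols = (["direction", "total_frequency", "mean_padj"]
                + [f"freq_{s}" for s in freq.sizes] + ["rank"])
        table = pd.DataFrame(columns=cols, index=pd.Index([], name="gene"))
    return StableGeneReport(
        table=table,
        direction_unstable=unstable,
        per_size_cutoff=config.per_size_cutoff,
        overall_cutoff=cutoff,
        config=config,
        group_order=freq.group_order,
    )


def calibrate_ratio(freq: FrequencyTable, full_de: "_de.DEResult | pd.DataFrame",
                    ratios: Sequence[float],
                    top_fracs: Sequence[float] = tuple(np.arange(1, 11) / 10),
                    ) -> pd.DataFrame:
    """Overlap of candidate stable sets with the top fractions of the
    full-cohort DEG list (ranked by ascending adjusted p).

    Returns one row per candidate ratio with the stable-set size and, for
    each top fraction, the percentage of stable genes contained in it.  The
    table is for the analyst; no ratio is chosen automatically.
    """
    if hasattr(full_de, "degs"):
        degs = full_de.degs
    else:
        degs = full_de
    if len(degs) == 0:
        raise ValueError("calibration undefined: full-cohort DEG list is empty")
    ranked = degs.sort_values("padj", kind="mergesort").index.tolist()

    rows = []
    for ratio in ratios:
        rep = call_stable_genes(freq, replace(freq.config, ratio=float(ratio),
                                              overall_ratio=None))
        stable = set(rep.stable_genes)
        row = {"ratio": float(ratio), "n_stable": len(stable)}
        for frac in top_fracs:
            k = math.ceil(frac * len(ranked))
            top = set(ranked[:k])
            row[f"overlap_top_{int(round(frac * 100))}pct"] = (
                100.0 * len(stable & top) / len(stable) if stable else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def saturation_curve(freq: FrequencyTable) -> pd.DataFrame:
    """Cumulative distinct DEGs and per-size novel-gene increments.

    Sizes are processed in ascending order; ``novel`` at a size counts the
    genes first detected at that size, so ``cumulative_distinct`` is
    non-decreasing and ``novel`` sums to it.
    """
    det = freq.detected_any.to_numpy()
    cum_seen = np.zeros(det.shape[0], dtype=bool)
    rows = []
    for si, size in enumerate(freq.sizes):
        new = det[:, si] & ~cum_seen
        cum_seen |= det[:, si]
        rows.append({
            "size": size,
            "mean_degs_per_draw": float(freq.mean_degs_per_draw.loc[size]),
            "novel": int(new.sum()),
            "cumulative_distinct": int(cum_seen.sum()),
        })
    return pd.DataFrame(rows).set_index("size")


def estimate_min_sample_size(curve: pd.DataFrame, tol_abs: int = 5,
                             tol_frac: float = 0.01) -> int | None:
    """Smallest size s such that every size >= s contributes at most
    ``max(tol_abs, tol_frac * cumulative)`` novel genes; ``None`` when the
    curve never settles ("not reached").

    This operationalizes the visual judgement of "few new genes appear":
    an absolute floor for small cohorts plus a fraction of the genes seen
    so far.
    """
    if len(curve) < 3:
        raise ValueError("saturation estimate needs a curve with >= 3 sizes")
    novel = curve["novel"].to_numpy()
    cum = curve["cumulative_distinct"].to_numpy()
    ok = novel <= np.maximum(tol_abs, tol_frac * cum)
    # find the first index from which ok holds through the end
    idx = None
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            idx = i
        else:
            break
    return int(curve.index[idx]) if idx is not None else None
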