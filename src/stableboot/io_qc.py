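"""Count-matrix I/O, RPKM normalization, sample-level QC and marker purity.

The central container is :class:`CountDataset`: a genes x samples matrix of
non-negative integer read counts together with per-sample metadata (subject,
group, optional replicate id and total mapped reads).  Everything downstream
— differential expression, bootstrap stability selection, clustering —
consumes this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

REQUIRED_META_COLUMNS = ("sample_id", "subject_id", "group")

#: Midbrain dopamine neuron identity markers (positive controls) and
#: glial contamination markers (astrocyte / microglia / OPC; negative
#: controls) used as editable defaults for purity checks.
DEFAULT_POSITIVE_MARKERS = (
    "EN1", "EN2", "FOXA2", "LMX1B", "PITX3", "NR4A2", "TH", "SLC6A3", "NEFH",
)
DEFAULT_NEGATIVE_MARKERS = ("MFGE8", "CX3CR1", "GPR17")


class ValidationError(ValueError):
    """Raised when a dataset or metadata table violates its contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata record for one sequenced sample."""

    sample_id: str
    subject_id: str
    group: str
    replicate: int | None = None
    total_reads: int | None = None
    extra: dict = field(default_factory=dict)


class CountDataset:
    """Genes x samples integer count matrix with validated sample metadata.

    Parameters
    ----------
    counts
        DataFrame with gene ids as the index and sample ids as columns.
        Entries must be finite, non-negative and integer valued.
    meta
        DataFrame with at least ``sample_id``, ``subject_id`` and ``group``
        columns covering every column of ``counts``.  Optional columns:
        ``replicate``, ``total_reads``.
    provenance
        Free-form processing notes carried through transformations.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame,
                 provenance: dict | None = None):
        counts, meta = _validate_counts_meta(counts, meta)
        self.counts = counts
        self.meta = meta
        self.provenance = dict(provenance or {})

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, sorted for a deterministic orientation."""
        return sorted(self.meta["group"].unique())

    @property
    def samples(self) -> list[SampleMeta]:
        out = []
        known = {"sample_id", "subject_id", "group", "replicate", "total_reads"}
        for sid in self.sample_ids:
            row = self.meta.loc[sid]
            rep = row.get("replicate")
            tot = row.get("total_reads")
            out.append(SampleMeta(
                sample_id=sid,
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                replicate=None if pd.isna(rep) else int(rep),
                total_reads=None if pd.isna(tot) else int(tot),
                extra={k: row[k] for k in self.meta.columns if k not in known},
            ))
        return out

    def group_of(self) -> pd.Series:
        """Group label per sample, ordered like the count columns."""
        return self.meta.loc[self.sample_ids, "group"]

    def subjects_with_both_groups(self) -> list[str]:
        """Subjects owning at least one sample in every group (paired units)."""
        grouped = self.meta.groupby("subject_id")["group"].agg(lambda g: set(g))
        full = set(self.groups)
        return sorted(s for s, g in grouped.items() if g == full)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountDataset":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in dataset: {missing}")
        meta = self.meta.loc[list(sample_ids)].copy()
        meta.insert(0, "sample_id", meta.index)
        return CountDataset(self.counts[list(sample_ids)].copy(), meta,
                            provenance=self.provenance)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CountDataset({self.n_genes} genes x {self.n_samples} samples,"
                f" groups={self.groups})")


def _validate_counts_meta(counts: pd.DataFrame, meta: pd.DataFrame):
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:10]}")
    if counts.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in count matrix")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = counts.columns[[not np.issubdtype(counts[c].dtype, np.number)
                              for c in counts.columns]]
        raise ValidationError(f"non-numeric count entries in columns: {list(bad)}")
    if not np.isfinite(vals).all():
        raise ValidationError("counts contain non-finite values")
    if (vals < 0).any():
        raise ValidationError("counts contain negative values")
    if not np.allclose(vals, np.round(vals)):
        raise ValidationError("counts must be integer valued")
    counts = counts.astype(np.int64)

    meta = meta.copy()
    for col in REQUIRED_META_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column '{col}'")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id rows in metadata")
    meta = meta.set_index("sample_id", drop=False)
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise ValidationError(
            f"metadata missing for samples: {missing}")
    meta = meta.loc[list(counts.columns)]
    key_cols = ["subject_id", "group"]
    if "replicate" in meta.columns:
        key_cols.append("replicate")
    if meta[key_cols].astype(str).duplicated().any():
        raise ValidationError(
            "duplicate (subject_id, group, replicate) metadata keys")
    return counts, meta.drop(columns=["sample_id"])


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt", ".tab"}:
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer matrix format from '{path.name}'; "
                     "pass format='tsv'|'csv'|'mtx'")


def _sidecar_paths(matrix_path: Path,
                   genes_path=None, samples_path=None) -> tuple[Path, Path]:
    stem = matrix_path.parent / matrix_path.stem
    genes = Path(genes_path) if genes_path else Path(f"{stem}.genes.txt")
    samples = Path(samples_path) if samples_path else Path(f"{stem}.samples.txt")
    return genes, samples


def read_counts(matrix_path, metadata_path, format: str | None = None,
                genes_path=None, samples_path=None) -> CountDataset:
    """Read a count matrix (TSV/CSV genes-in-rows, or MatrixMarket) plus
    a sample-metadata table into a validated :class:`CountDataset`.

    For MTX input, gene and sample names come from sidecar text files
    (one name per line), by default ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` next to the matrix.
    """
    matrix_path = Path(matrix_path)
    fmt = format or _infer_format(matrix_path)
    if fmt in {"tsv", "csv"}:
        sep = "\t" if fmt == "tsv" else ","
        counts = pd.read_csv(matrix_path, sep=sep, index_col=0)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        for col in counts.columns:
            converted = pd.to_numeric(counts[col], errors="coerce")
            bad = converted.isna() & counts[col].notna()
            if bad.any():
                genes = counts.index[bad].tolist()
                raise ValidationError(
                    f"non-numeric count entries for genes {genes[:5]} "
                    f"in column '{col}'")
            counts[col] = converted
    elif fmt == "mtx":
        genes_p, samples_p = _sidecar_paths(matrix_path, genes_path, samples_path)
        mat = scipy.io.mmread(matrix_path)
        genes = [line.strip() for line in Path(genes_p).read_text().splitlines()
                 if line.strip()]
        samples = [line.strip() for line in Path(samples_p).read_text().splitlines()
                   if line.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        counts = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format '{fmt}'")

    meta_path = Path(metadata_path)
    meta_sep = "," if meta_path.suffix.lower() == ".csv" else "\t"
    meta = pd.read_csv(meta_path, sep=meta_sep)
    return CountDataset(counts, meta)


def write_counts(dataset: CountDataset, matrix_path, metadata_path=None,
                 format: str | None = None,
                 genes_path=None, samples_path=None) -> None:
    """Write a dataset back to disk in any supported matrix format."""
    matrix_path = Path(matrix_path)
    fmt = format or _infer_format(matrix_path)
    if fmt in {"tsv", "csv"}:
        sep = "\t" if fmt == "tsv" else ","
        out = dataset.counts.copy()
        out.index.name = "gene"
        out.to_csv(matrix_path, sep=sep)
    elif fmt == "mtx":
        genes_p, samples_p = _sidecar_paths(matrix_path, genes_path, samples_path)
        coo = scipy.sparse.coo_matrix(dataset.counts.to_numpy())
        scipy.io.mmwrite(str(matrix_path), coo, field="integer")
        Path(genes_p).write_text("\n".join(dataset.gene_ids) + "\n")
        Path(samples_p).write_text("\n".join(dataset.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format '{fmt}'")
    if metadata_path is not None:
        meta = dataset.meta.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression transforms
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix (genes x samples) with a transform tag.

    ``transform_tag`` is one of ``rpkm``, ``cpm``, ``log2p1`` or
    ``zscore_rows`` and records how the values were derived so that
    downstream steps can assert their expectations.
    """

    values: pd.DataFrame
    transform_tag: str

    def log2p1(self) -> "ExpressionMatrix":
        if self.transform_tag not in {"rpkm", "cpm"}:
            raise ValueError("log2p1 expects linear-scale rpkm/cpm values")
        return ExpressionMatrix(np.log2(self.values + 1.0), "log2p1")

    def zscore_rows(self) -> "ExpressionMatrix":
        vals = self.values
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=0)
        sd = sd.replace(0.0, 1.0)  # constant rows stay at zero
        return ExpressionMatrix(vals.sub(mu, axis=0).div(sd, axis=0),
                                "zscore_rows")


def compute_rpkm(dataset: CountDataset, gene_lengths: Mapping[str, float],
                 denominator: str = "total_reads_meta") -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, s] = counts[g, s] / (length_kb[g] * mapped_millions[s])``.

    The per-sample denominator is the metadata ``total_reads`` column by
    default (the convention of read-to-gene summarisation tools, where the
    library total exceeds the in-matrix sum); pass
    ``denominator='column_sum'`` when no metadata totals exist.
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = dataset.gene_ids.difference(lengths.index)
    if len(missing):
        raise ValueError(f"gene lengths missing for: {list(missing[:5])}")
    lengths = lengths.loc[dataset.gene_ids]
    if (lengths <= 0).any() or not np.isfinite(lengths).all():
        bad = lengths.index[(lengths <= 0) | ~np.isfinite(lengths)].tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:5]}")

    if denominator == "total_reads_meta":
        if "total_reads" not in dataset.meta.columns or \
                dataset.meta["total_reads"].isna().any():
            raise ValueError(
                "metadata total_reads missing; use denominator='column_sum'")
        totals = dataset.meta["total_reads"].astype(float)
    elif denominator == "column_sum":
        totals = dataset.counts.sum(axis=0).astype(float)
    else:
        raise ValueError("denominator must be 'total_reads_meta' or 'column_sum'")
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive read totals for samples: {bad}")

    denom = np.outer(lengths.to_numpy() / 1e3, totals.to_numpy() / 1e6)
    rpkm = pd.DataFrame(dataset.counts.to_numpy() / denom,
                        index=dataset.gene_ids, columns=dataset.sample_ids)
    return ExpressionMatrix(rpkm, "rpkm")


def compute_cpm(dataset: CountDataset) -> ExpressionMatrix:
    """Counts per million (no length normalization), for length-free data."""
    totals = dataset.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    cpm = dataset.counts.div(totals / 1e6, axis=1)
    return ExpressionMatrix(cpm, "cpm")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-sample QC flags with the thresholds that produced them."""

    table: pd.DataFrame
    thresholds: dict
    passed: bool

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "passed": bool(self.passed),
            "samples": json.loads(self.table.to_json(orient="index")),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def qc_filter(dataset: CountDataset, expr: ExpressionMatrix,
              min_reads: int = 1_000_000, min_genes_rpkm1: int = 4600,
              min_nearest_corr: float = 0.7,
              rpkm_detect_threshold: float = 1.0) -> QCReport:
    """Sample-level QC: read depth, genes detected, nearest-sample correlation.

    A sample's nearest-sample correlation is the maximum Pearson correlation
    of its log2(RPKM+1) profile against every other sample; low values flag
    degraded or contaminated captures.  With a single sample the correlation
    is not assessable and is reported as missing.
    """
    if expr.transform_tag != "rpkm":
        raise ValueError("qc_filter expects an RPKM ExpressionMatrix")
    if list(expr.values.columns) != dataset.sample_ids:
        raise ValueError("expression matrix samples do not match dataset")

    if "total_reads" in dataset.meta.columns and \
            dataset.meta["total_reads"].notna().all():
        reads = dataset.meta["total_reads"].astype(float)
    else:
        reads = dataset.counts.sum(axis=0).astype(float)

    detected = (expr.values > rpkm_detect_threshold).sum(axis=0)

    n = dataset.n_samples
    if n >= 2:
        logv = np.log2(expr.values.to_numpy() + 1.0)
        corr = np.clip(np.corrcoef(logv.T), -1.0, 1.0)
        np.fill_diagonal(corr, -np.inf)
        nearest = pd.Series(corr.max(axis=1), index=dataset.sample_ids)
        # small numeric slack so duplicate columns pass a threshold of 1.0
        corr_ok = nearest >= min_nearest_corr - 1e-12
        assessable = True
    else:
        nearest = pd.Series([np.nan], index=dataset.sample_ids)
        corr_ok = pd.Series([False], index=dataset.sample_ids)
        assessable = False

    table = pd.DataFrame({
        "total_reads": reads,
        "reads_ok": reads >= min_reads,
        "genes_detected": detected,
        "genes_ok": detected >= min_genes_rpkm1,
        "nearest_sample_correlation": nearest,
        "corr_ok": corr_ok,
        "corr_assessable": assessable,
    }, index=pd.Index(dataset.sample_ids, name="sample_id"))
    thresholds = {
        "min_reads": min_reads,
        "min_genes_rpkm1": min_genes_rpkm1,
        "min_nearest_corr": min_nearest_corr,
        "rpkm_detect_threshold": rpkm_detect_threshold,
    }
    passed = bool(assessable and
                  table[["reads_ok", "genes_ok", "corr_ok"]].all().all())
    return QCReport(table=table, thresholds=thresholds, passed=passed)


def average_replicates(dataset: CountDataset) -> CountDataset:
    """Collapse technical/section replicates to one sample per (subject, group).

    Counts are averaged arithmetically and rounded half-up back to integers
    so that count-model assumptions downstream still hold; the rounding rule
    is recorded in the dataset provenance.  Idempotent: a dataset without
    replicates is returned unchanged.
    """
    meta = dataset.meta
    key = {s: (str(meta.loc[s, "subject_id"]), str(meta.loc[s, "group"]))
           for s in dataset.sample_ids}
    from collections import Counter
    sizes = Counter(key.values())
    if max(sizes.values()) <= 1:
        return dataset

    new_cols: dict[str, np.ndarray] = {}
    rows = []
    seen: set[tuple[str, str]] = set()
    for sid in dataset.sample_ids:
        k = key[sid]
        if k in seen:
            continue
        seen.add(k)
        members = [s for s in dataset.sample_ids if key[s] == k]
        subject, group = k
        if len(members) == 1:
            m = members[0]
            new_cols[m] = dataset.counts[m].to_numpy()
            row = meta.loc[m].to_dict()
            row["sample_id"] = m
            rows.append(row)
        else:
            reps = meta.loc[members, "replicate"] if "replicate" in meta.columns \
                else pd.Series([None] * len(members), index=members)
            if reps.notna().any() and reps.dropna().duplicated().any():
                raise ValidationError(
                    f"duplicate replicate ids within subject '{subject}' "
                    f"group '{group}'")
            mean = dataset.counts[members].to_numpy().mean(axis=1)
            new_id = f"{subject}--{group}"
            new_cols[new_id] = np.floor(mean + 0.5).astype(np.int64)
            row = {"sample_id": new_id, "subject_id": subject, "group": group,
                   "replicate": pd.NA}
            if "total_reads" in meta.columns:
                tot = meta.loc[members, "total_reads"].astype(float).mean()
                row["total_reads"] = int(np.floor(tot + 0.5))
            row["averaged_from"] = ";".join(members)
            rows.append(row)

    counts = pd.DataFrame(new_cols, index=dataset.gene_ids)
    new_meta = pd.DataFrame(rows)
    prov = dict(dataset.provenance)
    prov["replicate_averaging"] = "arithmetic mean, rounded half-up to integer"
    return CountDataset(counts, new_meta, provenance=prov)


# ---------------------------------------------------------------------------
# Marker purity
# ---------------------------------------------------------------------------

@dataclass
class MarkerPurityReport:
    table: pd.DataFrame
    missing_positive: list[str]
    missing_negative: list[str]
    thresholds: dict


def marker_panel_check(expr: ExpressionMatrix,
                       positive_markers: Iterable[str] = DEFAULT_POSITIVE_MARKERS,
                       negative_markers: Iterable[str] = DEFAULT_NEGATIVE_MARKERS,
                       min_rpkm: float = 1.0,
                       positive_min_fraction: float = 0.8,
                       negative_max_fraction: float = 0.2) -> MarkerPurityReport:
    """Check each sample for expression of cell-identity markers and absence
    of contamination markers.

    A sample passes when the fraction of positive markers expressed at or
    above ``min_rpkm`` is at least ``positive_min_fraction`` and the fraction
    of negative (contamination) markers so expressed is at most
    ``negative_max_fraction``.  Markers absent from the matrix are reported
    but not fatal unless every marker is absent.
    """
    positive = sorted(set(positive_markers))
    negative = sorted(set(negative_markers))
    if not positive or not negative:
        raise ValueError("marker lists must be non-empty")
    pos_found = [g for g in positive if g in expr.values.index]
    neg_found = [g for g in negative if g in expr.values.index]
    if not pos_found and not neg_found:
        raise ValueError("none of the supplied markers are present in the matrix")

    def fraction(genes):
        if not genes:
            return pd.Series(np.nan, index=expr.values.columns)
        return (expr.values.loc[genes] >= min_rpkm).mean(axis=0)

    pos_frac = fraction(pos_found)
    neg_frac = fraction(neg_found)
    ok = (pos_frac >= positive_min_fraction) & (neg_frac <= negative_max_fraction)
    ok = ok.fillna(False) & pos_frac.notna()
    table = pd.DataFrame({
        "positive_fraction": pos_frac,
        "negative_fraction": neg_frac,
        "pass": ok,
    })
    table.index.name = "sample_id"
    return MarkerPurityReport(
        table=table,
        missing_positive=[g for g in positive if g not in pos_found],
        missing_negative=[g for g in negative if g not in neg_found],
        thresholds={"min_rpkm": min_rpkm,
                    "positive_min_fraction": positive_min_fraction,
                    "negative_max_fraction": negative_max_fraction},
    )
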