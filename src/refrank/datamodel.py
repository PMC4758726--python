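"""Core data containers, TSV readers/writers and validation.

Two substrates flow through the pipeline:

* :class:`ExpressionMatrix` — a genes × stages RPKM matrix from bulk RNA-seq,
  the input to candidate screening.
* :class:`CtDataset` — a genes × samples × replicates table of qPCR threshold
  cycles (CT), tagged with the cDNA priming chemistry that produced it
  (oligo-dT = "OP", random primer = "RP"), the input to stability ranking.

All tabular I/O is TSV, UTF-8, "." decimal separator; gene identifiers are
opaque strings. Standard deviations throughout the package are sample SDs
(denominator n − 1) unless a function documents otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("refrank")

#: CT values outside this window are flagged (not rejected) during validation.
DEFAULT_CT_RANGE: tuple[float, float] = (5.0, 40.0)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    Defaults are the published screen settings: genes are called expressed at
    RPKM ≥ 0.17, stably expressed when RPKM_max/min < 2 and CV < 0.3,
    abundant when min RPKM > 40, and the five candidates with the smallest
    max/min ratio go forward. ``efficiency_base`` is the assumed per-cycle
    amplification factor (2.0 = perfect doubling).
    """

    expressed_threshold: float = 0.17
    max_min_ratio_limit: float = 2.0
    cv_limit: float = 0.3
    min_rpkm: float = 40.0
    top_n: int = 5
    efficiency_base: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("expressed_threshold", "max_min_ratio_limit", "cv_limit",
                     "min_rpkm", "efficiency_base"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A validated genes × stages matrix of non-negative RPKM values.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene ids and
    whose columns hold the ordered stage labels (order is taken from the
    source file; no chronology is inferred).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValidationError(f"duplicate stage label: {dup!r}")
        if data.shape[1] < 2:
            raise ValidationError("need at least 2 stages")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite RPKM at gene {data.index[r]!r}, stage {data.columns[c]!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative RPKM at gene {data.index[r]!r}, stage {data.columns[c]!r}")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def stage_labels(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_stages(self) -> int:
        return self.data.shape[1]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_stages} stages)"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and stage labels in the header.

    Raises :class:`ValidationError` naming the offending cell for duplicate
    gene ids, non-numeric cells and negative values. Row and column order are
    preserved.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        # float() keeps the round trip bit-exact (pd.to_numeric may be 1 ulp off)
        def parse(cell, gene):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValidationError(
                    f"missing value at gene {gene!r}, stage {col!r}")
            try:
                return float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric value at gene {gene!r}, stage {col!r}") from None

        numeric[col] = [parse(cell, gene)
                        for gene, cell in zip(raw.index, raw[col])]
    return ExpressionMatrix(numeric)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; float repr round-trips values bit-exactly."""
    m.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# CT dataset
# ---------------------------------------------------------------------------


@dataclass
class CtDataset:
    """Threshold-cycle measurements for a set of genes across samples.

    ``values`` has shape (genes, samples, replicates). Technical replicates
    are retained until :func:`collapse_replicates` averages them; after
    collapse the per-cell replicate SD is kept in ``replicate_sd``.
    ``group`` tags the priming chemistry ("OP" or "RP") or any other
    experimental batch analysed separately.
    ``range_flags`` lists (gene, sample, replicate, ct) tuples whose CT fell
    outside the plausibility window — flagged, never dropped.
    """

    gene_ids: list[str]
    sample_labels: list[str]
    values: np.ndarray
    group: str = "OP"
    replicate_sd: np.ndarray | None = None
    range_flags: list[tuple[str, str, int, float]] = field(default_factory=list)
    ct_range: tuple[float, float] = DEFAULT_CT_RANGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("CT values must be genes x samples x replicates")
        g, n, r = self.values.shape
        if len(self.gene_ids) != g or len(self.sample_labels) != n:
            raise ValidationError("axis labels do not match value dimensions")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids in CT dataset")
        if len(set(self.sample_labels)) != n:
            raise ValidationError("duplicate sample labels in CT dataset")
        if not np.isfinite(self.values).all():
            gi, si, ri = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite CT at gene {self.gene_ids[gi]!r}, "
                f"sample {self.sample_labels[si]!r}, replicate {ri + 1}")
        if not self.range_flags:
            lo, hi = self.ct_range
            out = np.argwhere((self.values < lo) | (self.values > hi))
            for gi, si, ri in out:
                self.range_flags.append(
                    (self.gene_ids[gi], self.sample_labels[si], int(ri) + 1,
                     float(self.values[gi, si, ri])))
            if self.range_flags:
                logger.warning("%d CT value(s) outside [%g, %g] in group %s",
                               len(self.range_flags), lo, hi, self.group)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    @property
    def is_collapsed(self) -> bool:
        return self.n_replicates == 1

    def ct_matrix(self) -> np.ndarray:
        """Genes × samples CT matrix; requires replicate depth 1."""
        if not self.is_collapsed:
            raise ValidationError(
                "dataset has replicates; call collapse_replicates first")
        return self.values[:, :, 0]

    def subset(self, gene_ids: Sequence[str]) -> "CtDataset":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CtDataset(list(gene_ids), list(self.sample_labels),
                         self.values[idx], group=self.group,
                         replicate_sd=None if self.replicate_sd is None
                         else self.replicate_sd[idx],
                         ct_range=self.ct_range)


def collapse_replicates(ds: CtDataset) -> CtDataset:
    """Average technical replicates to a single CT per (gene, sample).

    The cell value becomes the arithmetic mean of replicate CTs; the per-cell
    sample SD of the replicates is retained as metadata. Idempotent: a
    depth-1 dataset is returned unchanged.
    """
    if ds.is_collapsed:
        return ds
    mean = ds.values.mean(axis=2, keepdims=True)
    sd = ds.values.std(axis=2, ddof=1)
    return CtDataset(list(ds.gene_ids), list(ds.sample_labels), mean,
                     group=ds.group, replicate_sd=sd, ct_range=ds.ct_range)


def read_ct_dataset(path: str | Path, group: str = "OP", layout: str = "long",
                    ct_range: tuple[float, float] = DEFAULT_CT_RANGE) -> CtDataset:
    """Read a CT table in long or wide layout.

    Long layout: columns ``gene_id``, ``sample``, ``replicate``, ``ct``.
    Wide layout: columns ``gene_id``, ``replicate`` then one column per
    sample. The replicate structure must be complete — a missing
    (gene, sample) cell is a hard error listing the pair. CT values outside
    ``ct_range`` are recorded in the dataset's ``range_flags``, not dropped.
    """
    if layout == "long":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={"gene_id": str, "sample": str})
        required = {"gene_id", "sample", "replicate", "ct"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"long CT table needs columns {sorted(required)}")
    elif layout == "wide":
        wide = pd.read_csv(path, sep="\t", float_precision="round_trip",
                           dtype={"gene_id": str})
        sample_cols = [c for c in wide.columns if c not in ("gene_id", "replicate")]
        df = wide.melt(id_vars=["gene_id", "replicate"], value_vars=sample_cols,
                       var_name="sample", value_name="ct")
    else:
        raise ValidationError(f"unknown layout {layout!r}")

    genes = list(dict.fromkeys(df["gene_id"]))
    samples = list(dict.fromkeys(df["sample"]))
    reps = sorted(df["replicate"].unique())
    cube = df.set_index(["gene_id", "sample", "replicate"])["ct"]
    if cube.index.has_duplicates:
        g, s, r = cube.index[cube.index.duplicated()][0]
        raise ValidationError(f"duplicate CT entry for gene {g!r}, sample {s!r}")

    full = pd.MultiIndex.from_product([genes, samples, reps],
                                      names=["gene_id", "sample", "replicate"])
    cube = cube.reindex(full)
    if cube.isna().any():
        missing = sorted({(g, s) for g, s, _ in cube.index[cube.isna()]})
        raise ValidationError(f"missing CT for (gene, sample) pairs: {missing}")

    values = cube.to_numpy().reshape(len(genes), len(samples), len(reps))
    return CtDataset([str(g) for g in genes], [str(s) for s in samples],
                     values, group=group, ct_range=ct_range)


def write_ct_dataset(ds: CtDataset, path: str | Path) -> None:
    """Write a CT dataset in the long TSV layout."""
    rows = []
    for gi, g in enumerate(ds.gene_ids):
        for si, s in enumerate(ds.sample_labels):
            for ri in range(ds.n_replicates):
                rows.append((g, s, ri + 1, ds.values[gi, si, ri]))
    pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "ct"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcript-structure annotation used by the final screening filter.

    ``two_transcripts_overlap`` is only meaningful when ``transcript_count``
    is exactly 2 (it flags whether the two isoforms overlap, so a single
    primer pair can capture both).
    """

    gene_id: str
    transcript_count: int
    two_transcripts_overlap: bool = False

    def __post_init__(self) -> None:
        if self.transcript_count < 0:
            raise ValidationError(
                f"negative transcript count for {self.gene_id!r}")


def read_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a TSV with columns gene_id, transcript_count, two_transcripts_overlap."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = GeneAnnotation(str(row.gene_id), int(row.transcript_count),
                             bool(getattr(row, "two_transcripts_overlap", False)))
        if ann.gene_id in out:
            raise ValidationError(f"duplicate annotation for {ann.gene_id!r}")
        out[ann.gene_id] = ann
    return out


def write_annotation(ann: dict[str, GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.gene_id, a.transcript_count, a.two_transcripts_overlap)
         for a in ann.values()],
        columns=["gene_id", "transcript_count", "two_transcripts_overlap"],
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "DEFAULT_CT_RANGE", "ValidationError", "PipelineConfig",
    "ExpressionMatrix", "read_expression_matrix", "write_expression_matrix",
    "CtDataset", "collapse_replicates", "read_ct_dataset", "write_ct_dataset",
    "GeneAnnotation", "read_annotation", "write_annotation",
]
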