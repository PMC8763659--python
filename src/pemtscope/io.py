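"""Readers, writers and validated in-memory containers.

All tabular formats are plain TSV/CSV handled through pandas; gene sets
use the GMT convention (name, description, genes, tab-separated). Gene
identifiers are matched case-sensitively and no alias resolution is
attempted — inputs are assumed pre-mapped to a single symbol space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an explicit scale flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, index = gene ids, columns = sample ids.
    scale : {"linear", "log2"}
        Whether values are linear (TPM-like, nonnegative) or log2.
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {v.index[bad[0]]!r}, sample {v.columns[bad[1]]!r}"
            )
        if self.scale == LINEAR and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative linear-scale value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(), scale=self.scale)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class GeneSet:
    """A named gene list, e.g. the 15-gene common pEMT signature."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValidationError(f"gene set {self.name!r} contains duplicate genes")
        if len(self.genes) < 2:
            raise ValidationError(f"gene set {self.name!r} has fewer than 2 genes")

    @property
    def m(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClinicalTable:
    """Per-sample time-to-event data plus arbitrary covariates.

    ``data`` is indexed by sample id with at least columns ``time``
    (positive, months) and ``event`` (0 = censored, 1 = death/relapse).
    """

    data: pd.DataFrame

    TIME = "time"
    EVENT = "event"

    def __post_init__(self) -> None:
        df = self.data
        for col in (self.TIME, self.EVENT):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        bad_time = df.index[~(df[self.TIME] > 0)].tolist()
        if bad_time:
            raise ValidationError(f"non-positive survival time for samples {bad_time[:5]}")
        ev = df[self.EVENT]
        bad_event = df.index[~ev.isin([0, 1])].tolist()
        if bad_event:
            raise ValidationError(f"event indicator not in {{0,1}} for samples {bad_event[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data[self.TIME]

    @property
    def event(self) -> pd.Series:
        return self.data[self.EVENT]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=[self.TIME, self.EVENT])

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


@dataclass
class ReferenceProfile:
    """Reference expression of deconvolution signature genes per cell type.

    ``values``: genes x cell types, linear scale, nonnegative.
    ``weights``: per-gene nonnegative fit weights (default 1).
    ``mrna_content``: optional per-cell-type positive mRNA content used to
    renormalize fractions from mRNA proportions to cell proportions.
    """

    values: pd.DataFrame
    weights: pd.Series | None = None
    mrna_content: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValidationError("reference profile needs >= 1 gene and >= 1 cell type")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("reference profile values must be finite and nonnegative")
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.values.index)
        else:
            self.weights = self.weights.reindex(self.values.index)
            w = self.weights.to_numpy(dtype=float)
            if not np.isfinite(w).all() or (w < 0).any():
                raise ValidationError("gene weights must be finite and nonnegative")
        if self.mrna_content is not None:
            mc = self.mrna_content.reindex(self.values.columns).to_numpy(dtype=float)
            if not np.isfinite(mc).all() or (mc <= 0).any():
                raise ValidationError("mRNA contents must be finite and positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers


def _read_table(path, **kwargs) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, **kwargs)


def read_expression_matrix(path, scale: str = LINEAR) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV expression matrix.

    Duplicate gene rows are collapsed by arithmetic mean on the input
    scale (logged); non-numeric cells raise a parse error naming the
    offending location.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen = set()
    dupes = [c for c in header if c in seen or seen.add(c)]
    if dupes:
        raise ValidationError(f"duplicate sample ids in {path}: {dupes[:5]}")
    df = _read_table(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric or missing value at gene {gene!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene id(s) by mean: %s", len(dupes), dupes[:5])
        df = df.groupby(level=0, sort=False).mean()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale)


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one gene set per tab-separated line.

    Fields are name, description, then gene ids; duplicate genes within a
    line are deduplicated preserving first appearance.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT requires name, description and >= 1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            sets.append(GeneSet(name=name, description=desc, genes=deduped))
    return sets


def read_clinical_table(path) -> ClinicalTable:
    """Read a TSV clinical table (index = sample, columns incl. time, event).

    Categorical covariates keep the level order of first appearance.
    """
    df = _read_table(path)
    df.index = df.index.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            levels = list(dict.fromkeys(df[col].dropna()))
            df[col] = pd.Categorical(df[col], categories=levels)
    return ClinicalTable(df)


def read_reference_profile(path, weights_path=None, mrna_content_path=None) -> ReferenceProfile:
    """Read a genes x cell-types reference TSV, plus optional weights/contents."""
    values = _read_table(path).astype(float)
    weights = None
    if weights_path is not None:
        weights = _read_table(weights_path).iloc[:, 0].astype(float)
    mrna = None
    if mrna_content_path is not None:
        mrna = _read_table(mrna_content_path).iloc[:, 0].astype(float)
    return ReferenceProfile(values, weights=weights, mrna_content=mrna)


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def pemt_signature() -> GeneSet:
    """Return the bundled 15-gene common pEMT signature."""
    ref = resources.files("pemtscope.data").joinpath("pemt_signature.gmt")
    with resources.as_file(ref) as p:
        return read_gmt(p)[0]
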