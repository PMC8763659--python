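"""Rank-based single-sample signature scoring (Singscore).

For an up-regulated gene set of size ``m`` scored against a background of
``n`` ranked genes, each sample's score is the normalized, centered mean
rank of the set genes:

    score = (rbar - rmin) / (rmax - rmin) - 0.5

with rbar the mean rank of the set genes (ranks 1..n ascending, ties
averaged), rmin = (m + 1) / 2 and rmax = (2n - m + 1) / 2. The score lies
in [-0.5, 0.5]; under random placement its expectation is 0. The
accompanying dispersion is the scaled median absolute deviation of the
set genes' normalized ranks (rank / n), low when the signature genes sit
in a concerted block of the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)

#: consistency constant making the MAD match the SD for normal data
MAD_SCALE = 1.4826


@dataclass
class SingscoreTable:
    """Per-sample Singscores with rank-dispersion diagnostics.

    ``table`` is indexed by sample id with columns ``score`` and
    ``dispersion``; ``n_background`` is the number of genes ranked and
    ``m`` the signature size actually used.
    """

    table: pd.DataFrame
    n_background: int
    m: int

    def __post_init__(self) -> None:
        s = self.table["score"].to_numpy()
        if not np.isfinite(s).all():
            raise ValidationError("non-finite Singscore")
        if (s < -0.5 - 1e-12).any() or (s > 0.5 + 1e-12).any():
            raise ValidationError("Singscore outside [-0.5, 0.5]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def dispersion(self) -> pd.Series:
        return self.table["dispersion"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def rank_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Rank genes within each sample, ascending, average ties.

    Returns a genes x samples DataFrame of ranks in 1..n; a constant
    sample gets all ranks (n + 1) / 2.
    """
    if expr.n_genes < 2:
        raise ValidationError("ranking requires >= 2 genes")
    arr = expr.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite expression values")
    ranks = stats.rankdata(arr, method="average", axis=0)
    return pd.DataFrame(ranks, index=expr.values.index, columns=expr.values.columns)


def _resolve_set(genes_present: pd.Index, gene_set: GeneSet) -> list[str]:
    present = [g for g in gene_set.genes if g in genes_present]
    missing = [g for g in gene_set.genes if g not in genes_present]
    if missing:
        logger.warning(
            "gene set %r: dropping %d gene(s) absent from matrix: %s",
            gene_set.name, len(missing), missing[:10],
        )
    if len(present) < 2:
        raise ValidationError(
            f"gene set {gene_set.name!r} has < 2 genes present in the matrix"
        )
    return present


def singscore(ranks: pd.DataFrame, gene_set: GeneSet, mad_scale: float = MAD_SCALE) -> SingscoreTable:
    """Score every sample (column of ``ranks``) against an up gene set.

    Signature genes absent from the matrix are dropped with a warning and
    ``m`` recomputed; fewer than 2 surviving genes is an error.
    """
    n = ranks.shape[0]
    present = _resolve_set(ranks.index, gene_set)
    m = len(present)
    if m >= n:
        raise ValidationError("signature size must be smaller than the background")
    sub = ranks.loc[present]
    rbar = sub.mean(axis=0)
    rmin = (m + 1) / 2.0
    rmax = (2 * n - m + 1) / 2.0
    score = (rbar - rmin) / (rmax - rmin) - 0.5
    norm = sub.to_numpy() / n
    med = np.median(norm, axis=0)
    dispersion = mad_scale * np.median(np.abs(norm - med), axis=0)
    table = pd.DataFrame({"score": score, "dispersion": dispersion}, index=ranks.columns)
    return SingscoreTable(table=table, n_background=n, m=m)


def score_cohort(
    expr: ExpressionMatrix, gene_set: GeneSet, log2_transform: bool = True
) -> SingscoreTable:
    """Rank each sample and Singscore it against ``gene_set``.

    ``log2_transform`` applies log2(x + 1) to linear-scale input first.
    Ranks are invariant under this monotone transform, so scores do not
    change; the option mirrors the common preprocessing convention.
    """
    values = expr.values
    if log2_transform and expr.scale == "linear":
        values = np.log2(values + 1.0)
        expr = ExpressionMatrix(values, scale="log2")
    ranks = rank_matrix(expr)
    return singscore(ranks, gene_set)


def score_diagnostics(scores: SingscoreTable, ranks: pd.DataFrame, gene_set: GeneSet) -> dict:
    """Score-vs-dispersion diagnostics plus extreme-sample rank densities.

    Returns a dict with the (score, dispersion) table, the Spearman
    correlation between score and dispersion, and the normalized
    signature-gene ranks of the lowest- and highest-scoring samples (ties
    resolved toward the lexically smaller sample id).
    """
    present = _resolve_set(ranks.index, gene_set)
    n = ranks.shape[0]
    tab = scores.table
    ordered = tab.sort_values(["score", ], kind="mergesort")
    # stable sort; among tied extremes pick the smaller sample id
    lo_score = ordered["score"].iloc[0]
    hi_score = ordered["score"].iloc[-1]
    lo_ids = sorted(tab.index[tab["score"] == lo_score])
    hi_ids = sorted(tab.index[tab["score"] == hi_score])
    lo, hi = lo_ids[0], hi_ids[0]
    if tab["score"].nunique() < 2 or tab["dispersion"].nunique() < 2:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(tab["score"], tab["dispersion"])
    return {
        "table": tab.copy(),
        "score_dispersion_spearman": (float(rho), float(p)),
        "min_score_sample": lo,
        "max_score_sample": hi,
        "min_score_rank_density": (ranks.loc[present, lo] / n).rename("normalized_rank"),
        "max_score_rank_density": (ranks.loc[present, hi] / n).rename("normalized_rank"),
    }


def correlate_with_score(
    expr: ExpressionMatrix, scores: SingscoreTable, genes: list[str]
) -> pd.DataFrame:
    """Spearman rho (and two-sided t-approximation p) of genes vs score.

    Used to relate candidate regulators (e.g. EMT transcription factors
    such as SLUG/SNAI2) to per-sample pEMT scores.
    """
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:10]}")
    s = scores.scores.loc[expr.sample_ids]
    rows = []
    for g in genes:
        rho, p = stats.spearmanr(expr.values.loc[g], s)
        rows.append({"gene": g, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("gene")
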