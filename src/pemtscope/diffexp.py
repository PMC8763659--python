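"""High-vs-low differential expression and consensus intersection.

The built-in test is the two-sided Wilcoxon rank-sum per gene —
scale-robust and consistent with the rank-based score — with BH
adjustment across genes and log2 fold changes of group means
(pseudocount 1 on the linear scale). Results from external algorithms
(DESeq2, edgeR, limma-voom) enter through the same TSV schema
(gene, log2fc, p, q, direction), and the consensus keeps genes
significant in every table with agreeing direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet, ValidationError
from .survival import HIGH, LOW

UP, DOWN = "up", "down"


@dataclass
class DEResult:
    """One method's per-gene differential-expression table."""

    method: str
    table: pd.DataFrame  # index gene; columns log2fc, p, q, direction

    def __post_init__(self) -> None:
        t = self.table
        required = {"log2fc", "p", "q", "direction"}
        if not required.issubset(t.columns):
            raise ValidationError(f"DE table missing columns {required - set(t.columns)}")
        if ((t["q"] + 1e-12) < t["p"]).any():
            raise ValidationError("adjusted q must be >= raw p")
        sign_up = (t["direction"] == UP) & (t["log2fc"] < 0)
        sign_dn = (t["direction"] == DOWN) & (t["log2fc"] > 0)
        if (sign_up | sign_dn).any():
            raise ValidationError("direction inconsistent with fold-change sign")

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] <= q_threshold]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def read_de_result(path, method: str | None = None) -> DEResult:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DEResult(method=method or str(path), table=df)


@dataclass
class ConsensusDEG:
    """Genes significant with agreeing direction in every input table."""

    genes: list[str]
    directions: pd.Series  # gene -> up/down
    n_up: int
    n_down: int
    overlap_counts: dict[str, int] = field(default_factory=dict)


def two_group_de(
    expr: ExpressionMatrix, groups: pd.Series, method: str = "rank-sum"
) -> DEResult:
    """Per-gene two-sided rank-sum test, high vs low.

    ``groups`` labels samples "high"/"low" (others ignored); fold change
    is log2((mean_high + 1) / (mean_low + 1)) on the linear scale.
    """
    if method != "rank-sum":
        raise ValidationError(f"unknown built-in test {method!r}")
    groups = groups.loc[[s for s in groups.index if s in expr.values.columns]]
    hi = [s for s in groups.index if groups[s] == HIGH]
    lo = [s for s in groups.index if groups[s] == LOW]
    if len(hi) < 2 or len(lo) < 2:
        raise ValidationError("need >= 2 samples per group")
    values = expr.values
    if expr.scale == "log2":
        values = np.exp2(values)
    A = values[hi].to_numpy(dtype=float)
    B = values[lo].to_numpy(dtype=float)
    stat, p = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
    log2fc = np.log2((A.mean(axis=1) + 1.0) / (B.mean(axis=1) + 1.0))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    direction = np.where(log2fc >= 0, UP, DOWN)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "direction": direction}, index=values.index
    )
    return DEResult(method="rank-sum", table=table)


def consensus_degs(results: list[DEResult], q_threshold: float = 0.05) -> ConsensusDEG:
    """Intersect significant genes across tables, requiring one direction.

    A gene must reach q <= threshold in every table and carry the same
    direction everywhere; direction-discordant genes are excluded even if
    significant in all tables.
    """
    if not results:
        raise ValidationError("need >= 1 DE result table")
    sig_tables = [r.significant(q_threshold) for r in results]
    common: set[str] = set(sig_tables[0].index)
    for t in sig_tables[1:]:
        common &= set(t.index)
    genes, dirs = [], {}
    for g in sorted(common):
        ds = {t.loc[g, "direction"] for t in sig_tables}
        if len(ds) == 1:
            genes.append(g)
            dirs[g] = ds.pop()
    directions = pd.Series(dirs, dtype=object)
    return ConsensusDEG(
        genes=genes,
        directions=directions,
        n_up=int((directions == UP).sum()),
        n_down=int((directions == DOWN).sum()),
    )


def signature_overlap(consensus: ConsensusDEG, annotation_sets: list[GeneSet]) -> dict[str, int]:
    """Size of the consensus's intersection with each annotation set."""
    counts = {gs.name: len(set(consensus.genes) & set(gs.genes)) for gs in annotation_sets}
    consensus.overlap_counts.update(counts)
    return counts
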