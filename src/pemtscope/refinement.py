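"""Cohort refinement: drop fibroblast-contaminated samples.

The pEMT score is rank-based on bulk expression, so any non-malignant
cell type constitutively expressing signature genes — above all CAFs —
inflates it. The refinement step (1) selects which estimated cell-type
fractions linearly model the score, by backward/forward stepwise search
under the Gaussian AIC, (2) Ward-clusters patients on the selected
fractions, and (3) excludes every cluster whose mean CAF fraction reaches
the threshold (default 48.3%), then re-scores the retained cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .deconvolution import CellFractionTable, OTHER
from .io import ExpressionMatrix, ValidationError
from .scoring import SingscoreTable, score_cohort

CAF = "CAFs"
DEFAULT_CAF_THRESHOLD = 0.483


# ---------------------------------------------------------------------------
# stepwise AIC selection


def _gaussian_aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC = n ln(RSS/n) + 2 (k + 1) for an OLS fit with intercept.

    k counts the predictors (the intercept is always present and is the
    "+1"). RSS of 0 is floored at machine epsilon to keep the log finite.
    """
    n = y.shape[0]
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = max(float(resid @ resid), np.finfo(float).tiny)
    k = X.shape[1] if X.size else 0
    return n * np.log(rss / n) + 2 * (k + 1)


def stepwise_aic_select(
    response: pd.Series, covariates: pd.DataFrame
) -> tuple[list[str], list[tuple[int, str, str, float]]]:
    """Backward/forward stepwise linear-model selection under AIC.

    Starts from the full model; at each step evaluates every single-term
    deletion and addition and takes the move with the lowest AIC,
    breaking exact ties toward the smaller model; stops when no move
    improves. Returns (selected columns, trace of
    (step, action, term, aic)).
    """
    common = response.index.intersection(covariates.index)
    if len(common) <= covariates.shape[1] + 2:
        raise ValidationError("need n > number of candidates + 2")
    y = response.loc[common].to_numpy(dtype=float)
    X = covariates.loc[common].astype(float)
    arr = np.column_stack([np.ones(len(common)), X.to_numpy()])
    if np.linalg.cond(arr) > 1e10:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack().sort_values(ascending=False)
        offenders = list(pairs.index[0]) if len(pairs) else list(X.columns)
        raise ValidationError(f"collinear covariates (condition number > 1e10): {offenders}")

    candidates = list(X.columns)
    current = list(candidates)

    def aic_of(terms: list[str]) -> float:
        return _gaussian_aic(y, X[terms].to_numpy() if terms else np.empty((len(y), 0)))

    current_aic = aic_of(current)
    trace: list[tuple[int, str, str, float]] = [(0, "start", "<full>", current_aic)]
    step = 0
    while True:
        step += 1
        moves: list[tuple[float, int, str, str, list[str]]] = []
        for t in current:
            terms = [c for c in current if c != t]
            moves.append((aic_of(terms), len(terms), "drop", t, terms))
        for t in candidates:
            if t not in current:
                terms = current + [t]
                moves.append((aic_of(terms), len(terms), "add", t, terms))
        if not moves:
            break
        # lowest AIC; exact ties toward the smaller model, then term name
        moves.sort(key=lambda m: (m[0], m[1], m[3]))
        best_aic, _, action, term, terms = moves[0]
        if best_aic < current_aic - 1e-12 or (
            abs(best_aic - current_aic) <= 1e-12 and len(terms) < len(current)
        ):
            current, current_aic = terms, best_aic
            trace.append((step, action, term, current_aic))
        else:
            break
    return current, trace


class StepwiseLinearModel:
    """statsmodels-style facade: ``StepwiseLinearModel(y, X).fit()``."""

    def __init__(self, response: pd.Series, covariates: pd.DataFrame):
        self.response = response
        self.covariates = covariates

    def fit(self) -> "StepwiseResults":
        selected, trace = stepwise_aic_select(self.response, self.covariates)
        return StepwiseResults(self, selected, trace)


@dataclass
class StepwiseResults:
    model: StepwiseLinearModel
    selected: list[str]
    aic_trace: list[tuple[int, str, str, float]]

    @property
    def aic(self) -> float:
        return self.aic_trace[-1][3]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.aic_trace, columns=["step", "action", "term", "aic"])


# ---------------------------------------------------------------------------
# Ward clustering


def ward_cluster(
    fractions: pd.DataFrame, k: int = 2, variant: str = "ward.D2"
) -> pd.Series:
    """Agglomerative Ward clustering of samples, cut into k clusters.

    ``ward.D2`` is the variance-increase criterion on Euclidean input
    (scipy's "ward"); ``ward.D`` runs the same Lance-Williams update on
    unsquared distances. Cluster ids are relabelled deterministically by
    the smallest member index, so the partition is invariant to input
    order.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n = fractions.shape[0]
    if n < k:
        raise ValidationError(f"cannot cut {n} samples into {k} clusters")
    X = fractions.to_numpy(dtype=float)
    d = pdist(X)
    if variant == "ward.D2":
        Z = hierarchy.linkage(d, method="ward")
    elif variant == "ward.D":
        Z = hierarchy.linkage(d**2, method="ward")
    else:
        raise ValidationError(f"unknown Ward variant {variant!r}")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # canonical relabelling: order clusters by their smallest sample index
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    canon = np.array([order[lab] for lab in labels])
    return pd.Series(canon, index=fractions.index, name="cluster")


def exclude_high_fraction_cluster(
    assignments: pd.Series,
    fractions: pd.DataFrame,
    cell_type: str = CAF,
    threshold: float = DEFAULT_CAF_THRESHOLD,
) -> list[str]:
    """Samples in clusters whose mean ``cell_type`` fraction >= threshold."""
    if cell_type not in fractions.columns:
        raise ValidationError(f"cell type {cell_type!r} not in fraction table")
    excluded: list[str] = []
    for cluster_id, members in assignments.groupby(assignments):
        ids = list(members.index)
        if fractions.loc[ids, cell_type].mean() >= threshold:
            excluded.extend(ids)
    return sorted(excluded)


# ---------------------------------------------------------------------------
# full refinement


@dataclass
class RefinementReport:
    """Audit record of one refinement pass."""

    selected_cell_types: list[str]
    aic_trace: list[tuple[int, str, str, float]]
    cluster_assignments: pd.Series
    excluded_samples: list[str]
    non_converged_samples: list[str]
    retained_samples: list[str]
    caf_threshold: float
    spearman_before: pd.DataFrame  # cell type -> rho, p vs score
    spearman_after: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "selected_cell_types": self.selected_cell_types,
            "aic_trace": [list(t) for t in self.aic_trace],
            "cluster_assignments": {str(k): int(v) for k, v in self.cluster_assignments.items()},
            "excluded_samples": list(self.excluded_samples),
            "non_converged_samples": list(self.non_converged_samples),
            "retained_samples": list(self.retained_samples),
            "caf_threshold": self.caf_threshold,
            "spearman_before": self.spearman_before.to_dict(orient="index"),
            "spearman_after": self.spearman_after.to_dict(orient="index"),
        }


def _spearman_table(
    scores: pd.Series, fractions: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    rows = {}
    for ct in fractions.columns:
        rho, p = stats.spearmanr(scores.loc[samples], fractions.loc[samples, ct])
        rows[ct] = {"rho": float(rho), "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")


def refine_cohort(
    expr: ExpressionMatrix,
    scores: SingscoreTable,
    fractions: CellFractionTable,
    gene_set,
    caf_threshold: float = DEFAULT_CAF_THRESHOLD,
    k: int = 2,
    cell_type: str = CAF,
    ward_variant: str = "ward.D2",
) -> tuple[RefinementReport, ExpressionMatrix, SingscoreTable]:
    """Drop non-converged samples, select, cluster, exclude, re-score.

    Returns the report, the retained expression matrix and the Singscores
    recomputed on the retained samples. Exclusion is conditional: when no
    cluster reaches the CAF threshold nothing is excluded.
    """
    conv = fractions.converged
    non_converged = sorted(conv.index[~conv].tolist())
    kept = [s for s in expr.sample_ids if conv.get(s, False)]
    if len(kept) < 3:
        raise ValidationError("too few converged samples to refine")
    frac = fractions.fractions.loc[kept]
    sc = scores.scores.loc[kept]

    # the "otherCells" remainder is the exact complement of the named types,
    # so keeping it alongside them would alias the intercept; the named
    # fractions carry the same information
    candidates = frac.drop(columns=[OTHER], errors="ignore")
    selected, trace = stepwise_aic_select(sc, candidates)
    cluster_cols = selected if selected else list(frac.columns)
    assignments = ward_cluster(frac[cluster_cols], k=k, variant=ward_variant)
    excluded = exclude_high_fraction_cluster(
        assignments, frac, cell_type=cell_type, threshold=caf_threshold
    )
    retained = [s for s in kept if s not in set(excluded)]
    if len(retained) < 3:
        raise ValidationError("refinement excluded nearly the whole cohort")

    before = _spearman_table(scores.scores, fractions.fractions, kept)
    after = _spearman_table(scores.scores, fractions.fractions, retained)

    retained_expr = expr.subset_samples(retained)
    rescored = score_cohort(retained_expr, gene_set)
    report = RefinementReport(
        selected_cell_types=selected,
        aic_trace=trace,
        cluster_assignments=assignments,
        excluded_samples=excluded,
        non_converged_samples=non_converged,
        retained_samples=retained,
        caf_threshold=caf_threshold,
        spearman_before=before,
        spearman_after=after,
    )
    return report, retained_expr, rescored


class CohortRefinement:
    """Model-style facade over :func:`refine_cohort`."""

    def __init__(
        self,
        expr: ExpressionMatrix,
        scores: SingscoreTable,
        fractions: CellFractionTable,
        gene_set,
        caf_threshold: float = DEFAULT_CAF_THRESHOLD,
        k: int = 2,
        cell_type: str = CAF,
        ward_variant: str = "ward.D2",
    ):
        self.expr = expr
        self.scores = scores
        self.fractions = fractions
        self.gene_set = gene_set
        self.caf_threshold = caf_threshold
        self.k = k
        self.cell_type = cell_type
        self.ward_variant = ward_variant

    def fit(self):
        report, retained_expr, rescored = refine_cohort(
            self.expr,
            self.scores,
            self.fractions,
            self.gene_set,
            caf_threshold=self.caf_threshold,
            k=self.k,
            cell_type=self.cell_type,
            ward_variant=self.ward_variant,
        )
        return RefinementResults(self, report, retained_expr, rescored)


@dataclass
class RefinementResults:
    model: CohortRefinement
    report: RefinementReport
    retained_expr: ExpressionMatrix
    rescored: SingscoreTable

    def summary(self) -> pd.DataFrame:
        rep = self.report
        rows = []
        for ct in rep.spearman_before.index:
            rows.append(
                {
                    "cell_type": ct,
                    "selected": ct in rep.selected_cell_types,
                    "rho_before": rep.spearman_before.loc[ct, "rho"],
                    "rho_after": rep.spearman_after.loc[ct, "rho"],
                }
            )
        return pd.DataFrame(rows).set_index("cell_type")
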