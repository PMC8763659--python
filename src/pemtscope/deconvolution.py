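"""Reference-based deconvolution of bulk expression into cell-type fractions.

Follows the EPIC formulation: for each sample, the linear-scale bulk
expression b over a set of signature (marker) genes is modelled as a
nonnegative mixture of reference cell-type profiles R, minimizing the
weighted least squares

    min_f  sum_g  w_g (b_g - sum_c f_c R_gc)^2
    s.t.   f_c >= 0,  sum_c f_c <= 1,

and attributing the remainder 1 - sum_c f_c to an uncharacterized
"otherCells" compartment (tumor cells, here) assumed not to express the
marker genes. Fractions can optionally be renormalized by per-cell-type
mRNA content to convert mRNA proportions into cell proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ExpressionMatrix, ReferenceProfile, ValidationError

OTHER = "otherCells"

#: constraint-violation bound below which a solution counts as converged
CONSTRAINT_TOL = 1e-8
#: projected-gradient norm bound for the KKT check
KKT_TOL = 1e-6


@dataclass
class CellFractionTable:
    """Per-sample estimated fractions of the reference cell types.

    ``fractions`` is samples x (cell types + "otherCells"); ``converged``
    and ``fit_residual`` are per-sample solver diagnostics. Rows sum to 1.
    """

    fractions: pd.DataFrame
    converged: pd.Series
    fit_residual: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < -1e-9).any():
            raise ValidationError("negative cell fraction")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("fractions do not sum to 1")
        if OTHER not in self.fractions.columns:
            raise ValidationError(f"missing {OTHER!r} column")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_types(self) -> list[str]:
        return [c for c in self.fractions.columns if c != OTHER]

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["converged"] = self.converged
        out["fit_residual"] = self.fit_residual
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def transform_expression(expr: ExpressionMatrix, mode: str = "none") -> ExpressionMatrix:
    """Element-wise pre-deconvolution transform.

    ``square`` squares normalized (micro)array values; ``exp2``
    un-logs log2 data. Either sets the scale flag to linear.
    """
    if mode == "none":
        return expr
    if mode == "exp2":
        if expr.scale == "linear":
            import warnings

            warnings.warn("exp2 applied to an already-linear matrix", stacklevel=2)
        return ExpressionMatrix(np.exp2(expr.values), scale="linear")
    if mode == "square":
        return ExpressionMatrix(expr.values**2, scale="linear")
    raise ValidationError(f"unknown transform mode {mode!r}")


def _solve_one(
    b: np.ndarray, R: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Solve one sample's constrained weighted least squares.

    Reformulated with an explicit slack fraction s = 1 - sum(f) >= 0 so
    the feasible set is the simplex; solved by nonnegative least squares
    on the weighted design augmented with a heavily weighted row encoding
    sum(f) + s = 1, then polished with SLSQP. Returns (f, residual,
    converged) where converged requires solver success, constraint
    violation < 1e-8 and projected-gradient norm < 1e-6.
    """
    n_types = R.shape[1]
    sw = np.sqrt(w)
    A = sw[:, None] * R
    y = sw * b
    scale = max(np.abs(y).max(), 1.0)
    penalty = 1e6 * scale
    # augmented NNLS over (f, slack): penalty row enforces sum + slack = 1
    A_aug = np.zeros((A.shape[0] + 1, n_types + 1))
    A_aug[:-1, :n_types] = A
    A_aug[-1, :] = penalty
    y_aug = np.concatenate([y, [penalty]])
    x0, _ = optimize.nnls(A_aug, y_aug)
    f0 = np.clip(x0[:n_types], 0.0, None)
    if f0.sum() > 1.0:
        f0 = f0 / f0.sum()

    def objective(f):
        r = b - R @ f
        return float(np.sum(w * r * r))

    def grad(f):
        r = b - R @ f
        return -2.0 * (R.T @ (w * r))

    cons = [{"type": "ineq", "fun": lambda f: 1.0 - f.sum(), "jac": lambda f: -np.ones_like(f)}]
    res = optimize.minimize(
        objective,
        f0,
        jac=grad,
        bounds=[(0.0, 1.0)] * n_types,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    f = np.clip(res.x, 0.0, None)
    violation = max(0.0, f.sum() - 1.0)
    if violation > 0:
        f = f / f.sum()
        violation = 0.0
    g = grad(f)
    # projected gradient: zero out components blocked by active constraints
    pg = g.copy()
    at_zero = f <= 1e-12
    pg[at_zero & (g > 0)] = 0.0
    if 1.0 - f.sum() <= 1e-12:
        # on the simplex face: project onto the sum(f)=1 tangent space over
        # free coordinates
        free = ~(at_zero & (g > 0))
        if free.any():
            pg[free] -= pg[free].mean()
    gnorm = float(np.linalg.norm(pg)) / max(scale**2, 1.0)
    # the KKT residual is the authoritative optimality certificate; SLSQP's
    # status can report line-search stalls on the simplex boundary even when
    # first-order conditions hold to machine precision
    converged = violation < CONSTRAINT_TOL and gnorm < KKT_TOL
    residual = float(np.sqrt(objective(f)))
    return f, residual, converged


def deconvolve_sample(
    bulk: pd.Series, ref: ReferenceProfile, renormalize_mrna: bool | None = None
) -> tuple[pd.Series, float, bool]:
    """Estimate cell-type fractions of one sample.

    ``bulk`` is the sample's linear expression indexed by gene; only the
    reference's signature genes are used. Returns (fractions including
    "otherCells", fit residual, converged flag). An all-zero bulk over
    the signature genes yields fractions 0 with other = 1.
    """
    genes = [g for g in ref.gene_ids if g in bulk.index]
    if len(genes) < len(ref.cell_types):
        raise ValidationError(
            f"{len(genes)} signature gene(s) available for {len(ref.cell_types)} "
            "cell types: underdetermined"
        )
    b = bulk.loc[genes].to_numpy(dtype=float)
    if (b < 0).any():
        raise ValidationError("bulk expression must be nonnegative (linear scale)")
    R = ref.values.loc[genes].to_numpy(dtype=float)
    w = ref.weights.loc[genes].to_numpy(dtype=float)
    if not b.any():
        f = np.zeros(len(ref.cell_types))
        out = pd.Series(np.append(f, 1.0), index=ref.cell_types + [OTHER])
        return out, 0.0, True
    f, residual, converged = _solve_one(b, R, w)
    if renormalize_mrna is None:
        renormalize_mrna = ref.mrna_content is not None
    if renormalize_mrna:
        if ref.mrna_content is None:
            raise ValidationError("mRNA renormalization requested without mRNA contents")
        mc = ref.mrna_content.loc[ref.cell_types].to_numpy(dtype=float)
        other = 1.0 - f.sum()
        adj = np.append(f / mc, other)  # otherCells content treated as 1
        adj = adj / adj.sum() if adj.sum() > 0 else adj
        out = pd.Series(adj, index=ref.cell_types + [OTHER])
        return out, residual, converged
    out = pd.Series(np.append(f, 1.0 - f.sum()), index=ref.cell_types + [OTHER])
    return out, residual, converged


def deconvolve_cohort(
    expr: ExpressionMatrix,
    ref: ReferenceProfile,
    transform: str = "none",
    renormalize_mrna: bool | None = None,
) -> CellFractionTable:
    """Deconvolve every sample after the requested transform.

    Non-converged samples are retained but flagged; downstream cohort
    refinement drops them.
    """
    expr = transform_expression(expr, transform)
    rows, conv, resid = {}, {}, {}
    for s in expr.sample_ids:
        f, r, ok = deconvolve_sample(expr.values[s], ref, renormalize_mrna=renormalize_mrna)
        rows[s] = f
        conv[s] = ok
        resid[s] = r
    fractions = pd.DataFrame(rows).T
    fractions.index.name = "sample"
    return CellFractionTable(
        fractions=fractions,
        converged=pd.Series(conv, name="converged"),
        fit_residual=pd.Series(resid, name="fit_residual"),
    )


class Deconvolution:
    """Model-style wrapper: ``Deconvolution(expr, ref).fit()``.

    Thin statsmodels-flavoured facade over :func:`deconvolve_cohort`.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        ref: ReferenceProfile,
        transform: str = "none",
        renormalize_mrna: bool | None = None,
    ):
        self.expr = expr
        self.ref = ref
        self.transform = transform
        self.renormalize_mrna = renormalize_mrna

    def fit(self) -> "DeconvolutionResults":
        table = deconvolve_cohort(
            self.expr, self.ref, transform=self.transform, renormalize_mrna=self.renormalize_mrna
        )
        return DeconvolutionResults(self, table)


class DeconvolutionResults:
    def __init__(self, model: Deconvolution, table: CellFractionTable):
        self.model = model
        self.table = table

    @property
    def fractions(self) -> pd.DataFrame:
        return self.table.fractions

    def summary(self) -> pd.DataFrame:
        """Per-cell-type mean/sd fractions plus convergence counts."""
        desc = self.table.fractions.agg(["mean", "std", "min", "max"]).T
        desc["n_converged"] = int(self.table.converged.sum())
        desc["n_samples"] = len(self.table.converged)
        return desc
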