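"""Survival modelling: Cox PH screen, 40/40 dichotomization, KM/logrank.

The clinical workflow is: screen candidate covariates one at a time with
a univariable Cox proportional-hazards model (Wald p <= 0.05; optionally
restricted to risk factors, HR > 1), fit the retained terms jointly in a
multivariable Cox model, and visualize the score's effect by labelling
the lowest 40% of scores "low", the highest 40% "high" (middle 20%
excluded) and comparing Kaplan-Meier curves with the logrank test.
Fits are delegated to lifelines (Efron tie handling by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceError

from .io import ClinicalTable, ValidationError

LOW, HIGH, MIDDLE = "low", "high", "excluded-middle"


@dataclass
class CoxFit:
    """One fitted Cox proportional-hazards model.

    ``table`` has one row per term: hr, ci_low, ci_high, wald_p,
    relevant. Model-level statistics: aic (partial-likelihood AIC),
    concordance, n, plus an optional logrank p for group terms.
    """

    terms: list[str]
    table: pd.DataFrame
    aic: float
    concordance: float
    n: int
    logrank_p: float | None = None

    def __post_init__(self) -> None:
        t = self.table
        if ((t["ci_low"] > t["hr"] + 1e-9) | (t["hr"] > t["ci_high"] + 1e-9)).any():
            raise ValidationError("CI does not bracket the hazard ratio")
        if ((t["wald_p"] < 0) | (t["wald_p"] > 1)).any():
            raise ValidationError("Wald p outside [0, 1]")

    @property
    def hr(self) -> pd.Series:
        return self.table["hr"]

    @property
    def wald_p(self) -> pd.Series:
        return self.table["wald_p"]

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out.attrs.update({"aic": self.aic, "concordance": self.concordance, "n": self.n})
        return out


@dataclass
class Stratification:
    """40/40 score groups (or their cross with a second factor)."""

    groups: pd.Series  # sample -> group label
    quantiles: tuple[float, float]
    logrank_p: float | None = None
    median_survival: dict[str, float | None] = field(default_factory=dict)
    curves: pd.DataFrame | None = None  # time, at_risk, survival, group

    def samples_in(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])


def _type7_position(n: int, p: float) -> float:
    return 1.0 + (n - 1) * p


def dichotomize_by_quantiles(
    scores: pd.Series, lower: float = 0.4, upper: float = 0.6
) -> Stratification:
    """Label the lowest ``lower`` fraction "low", highest 1-``upper`` "high".

    Quantiles are type-7 (linear interpolation). Group sizes equal the
    type-7 position counts even under ties at the boundary value, which
    are admitted in ascending sample-id order; a sample sitting exactly
    on a shared lower==upper quantile goes to "low".
    """
    if not 0 < lower <= upper < 1:
        raise ValidationError("need 0 < lower <= upper < 1")
    s = scores.astype(float)
    n = len(s)
    if n < 3:
        raise ValidationError("need >= 3 samples to stratify")
    if float(s.max() - s.min()) == 0.0:
        raise ValidationError("degenerate quantiles: all scores identical")
    q_low = float(np.quantile(s.to_numpy(), lower))
    q_high = float(np.quantile(s.to_numpy(), upper))

    h_low = _type7_position(n, lower)
    n_low = int(np.floor(h_low))
    h_high = _type7_position(n, upper)
    if h_high == np.floor(h_high):
        n_high = n - int(h_high) + 1
    else:
        n_high = n - int(np.floor(h_high))

    # ascending by (score, sample id): ties resolved by id order
    order = sorted(s.index, key=lambda i: (s[i], str(i)))
    low_ids = set(order[:n_low])
    high_ids = set(order[n - n_high:])
    overlap = low_ids & high_ids  # only possible when lower == upper, n odd
    high_ids -= overlap
    labels = pd.Series(MIDDLE, index=s.index, name="group", dtype=object)
    labels.loc[list(low_ids)] = LOW
    labels.loc[list(high_ids)] = HIGH
    # sanity: low group must not out-score the low quantile except via ties
    assert s.loc[list(low_ids)].max() <= q_low + 1e-12 or len(set(s)) < n
    assert s.loc[list(high_ids)].min() >= q_high - 1e-12 or len(set(s)) < n
    return Stratification(groups=labels, quantiles=(lower, upper))


def _fit_cox(clinical: ClinicalTable, terms: list[str]) -> CoxPHFitter:
    df = clinical.data[[ClinicalTable.TIME, ClinicalTable.EVENT, *terms]].copy()
    for t in terms:
        if isinstance(df[t].dtype, pd.CategoricalDtype):
            codes = df[t].cat.codes
            if (codes < 0).any():
                raise ValidationError(f"missing values in covariate {t!r}")
            df[t] = codes.astype(float)
    arr = df[terms].to_numpy(dtype=float)
    if len(terms) > 1:
        centered = arr - arr.mean(axis=0)
        if np.linalg.cond(centered) > 1e10:
            raise ValidationError(f"collinear covariates among {terms}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=ClinicalTable.TIME, event_col=ClinicalTable.EVENT)
    except ConvergenceError as err:
        raise ValidationError(f"Cox model did not converge for {terms}: {err}") from err
    return cph


def _cox_result(cph: CoxPHFitter, clinical: ClinicalTable, terms: list[str]) -> CoxFit:
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "wald_p": summ["p"],
        }
    )
    table.index.name = "term"
    return CoxFit(
        terms=terms,
        table=table,
        aic=float(cph.AIC_partial_),
        concordance=float(cph.concordance_index_),
        n=len(clinical.data),
    )


def cox_univariable_screen(
    clinical: ClinicalTable,
    candidates: list[str],
    alpha: float = 0.05,
    risk_factor_mode: bool = False,
) -> list[CoxFit]:
    """One single-covariate Cox fit per candidate, flagged for relevance.

    relevant <=> Wald p <= alpha, additionally requiring HR > 1 when
    ``risk_factor_mode`` is on (the convention for accepting covariates
    as risk factors rather than protective ones).
    """
    fits = []
    for cand in candidates:
        if cand not in clinical.data.columns:
            raise KeyError(f"covariate {cand!r} not in clinical table")
        cph = _fit_cox(clinical, [cand])
        fit = _cox_result(cph, clinical, [cand])
        relevant = fit.table["wald_p"] <= alpha
        if risk_factor_mode:
            relevant &= fit.table["hr"] > 1.0
        fit.table["relevant"] = relevant
        fits.append(fit)
    return fits


def cox_multivariable(clinical: ClinicalTable, terms: list[str]) -> CoxFit:
    """Joint Cox PH fit over the screened terms."""
    if not terms:
        raise ValidationError("no terms for the multivariable model")
    cph = _fit_cox(clinical, list(terms))
    return _cox_result(cph, clinical, list(terms))


def _km_curves(clinical: ClinicalTable, groups: pd.Series) -> tuple[pd.DataFrame, dict]:
    curves = []
    medians: dict[str, float | None] = {}
    for label in sorted(groups.unique()):
        ids = groups.index[groups == label]
        sub = clinical.subset(list(ids))
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, event_observed=sub.event, label=str(label))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves.append(
            pd.DataFrame(
                {
                    "time": surv.index,
                    "at_risk": at_risk.to_numpy(),
                    "survival": surv.to_numpy(),
                    "group": str(label),
                }
            )
        )
        med = kmf.median_survival_time_
        medians[str(label)] = None if np.isinf(med) else float(med)
    return pd.concat(curves, ignore_index=True), medians


def km_logrank(clinical: ClinicalTable, groups: pd.Series) -> Stratification:
    """Kaplan-Meier curves per group plus the g-group logrank test.

    Median survival is the first time S(t) <= 0.5; groups whose curve
    never reaches 0.5 get ``None``.
    """
    groups = groups.loc[[s for s in groups.index if s in clinical.data.index]]
    use = groups[groups != MIDDLE]
    if use.nunique() < 2:
        raise ValidationError("logrank needs >= 2 non-empty groups")
    sub = clinical.subset(list(use.index))
    res = multivariate_logrank_test(sub.time, use.loc[sub.sample_ids], sub.event)
    curves, medians = _km_curves(sub, use)
    return Stratification(
        groups=use,
        quantiles=(np.nan, np.nan),
        logrank_p=float(res.p_value),
        median_survival=medians,
        curves=curves,
    )


def stratified_km(
    clinical: ClinicalTable, score_groups: pd.Series, second_factor: str
) -> Stratification:
    """Cross score groups with a binary factor; overall 4-group logrank.

    A constant factor collapses to the plain 2-group comparison. An empty
    cross cell is an error naming the cell.
    """
    if second_factor not in clinical.data.columns:
        raise KeyError(f"covariate {second_factor!r} not in clinical table")
    use = score_groups[score_groups != MIDDLE]
    use = use.loc[[s for s in use.index if s in clinical.data.index]]
    fac = clinical.data.loc[use.index, second_factor]
    fac_str = fac.astype(str)
    levels = list(dict.fromkeys(fac_str))
    if len(levels) == 1:
        return km_logrank(clinical, use)
    if len(levels) != 2:
        raise ValidationError(f"second factor must be binary, got levels {levels}")
    crossed = use.astype(str) + "/" + fac_str
    for g in sorted(use.unique()):
        for lv in levels:
            cell = f"{g}/{lv}"
            if (crossed == cell).sum() == 0:
                raise ValidationError(f"empty stratification cell {cell!r}")
    return km_logrank(clinical, crossed.rename("group"))
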