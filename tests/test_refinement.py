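from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform, pdist

from pemtscope.deconvolution import CellFractionTable, OTHER
from pemtscope.io import GeneSet, ValidationError
from pemtscope.refinement import (
    StepwiseLinearModel,
    _gaussian_aic,
    exclude_high_fraction_cluster,
    refine_cohort,
    stepwise_aic_select,
    ward_cluster,
)
from pemtscope.scoring import score_cohort
from pemtscope.simulate import make_reference_profiles, signature_genes, simulate_cohort
from pemtscope.deconvolution import deconvolve_cohort


def random_covariates(n=200, k=6, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, k)),
        columns=[f"x{j}" for j in range(k)],
        index=[f"s{i}" for i in range(n)],
    )
    return rng, X


def test_perfect_signal_is_selected():
    rng, X = random_covariates()
    X = X.rename(columns={"x0": "CAFs"})
    y = 2.0 * X["CAFs"]
    selected, trace = stepwise_aic_select(y, X)
    assert "CAFs" in selected
    aics = [t[3] for t in trace]
    assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))


def test_local_optimality_at_termination():
    rng, X = random_covariates(seed=3)
    y = pd.Series(
        1.5 * X["x1"] - 0.8 * X["x4"] + rng.normal(scale=1.0, size=len(X)), index=X.index
    )
    selected, trace = stepwise_aic_select(y, X)
    final_aic = trace[-1][3]
    yv = y.to_numpy()

    def aic(terms):
        return _gaussian_aic(yv, X[list(terms)].to_numpy() if terms else np.empty((len(X), 0)))

    for t in selected:
        assert aic([c for c in selected if c != t]) >= final_aic - 1e-9
    for t in X.columns:
        if t not in selected:
            assert aic(selected + [t]) >= final_aic - 1e-9


def test_matches_exhaustive_best_subset_oracle():
    """On a fixed 6-covariate instance the stepwise optimum equals the
    best of all 64 subsets by AIC."""
    rng, X = random_covariates(n=150, seed=42)
    y = pd.Series(
        0.9 * X["x0"] + 0.5 * X["x2"] + rng.normal(scale=0.7, size=len(X)), index=X.index
    )
    selected, trace = stepwise_aic_select(y, X)
    yv = y.to_numpy()

    def aic(terms):
        return _gaussian_aic(yv, X[list(terms)].to_numpy() if terms else np.empty((len(X), 0)))

    best = min(
        (subset for r in range(7) for subset in combinations(X.columns, r)),
        key=lambda s: aic(s),
    )
    assert aic(selected) == pytest.approx(aic(best), abs=1e-9)
    assert set(selected) == set(best)


def test_collinear_covariates_error():
    rng, X = random_covariates(n=100, k=3, seed=1)
    X["x2"] = 2.0 * X["x0"]
    y = pd.Series(rng.normal(size=len(X)), index=X.index)
    with pytest.raises(ValidationError, match="collinear"):
        stepwise_aic_select(y, X)


def test_stepwise_model_facade():
    rng, X = random_covariates(seed=9)
    y = pd.Series(X["x3"] + rng.normal(scale=0.5, size=len(X)), index=X.index)
    res = StepwiseLinearModel(y, X).fit()
    assert "x3" in res.selected
    assert res.summary()["aic"].iloc[-1] == res.aic


# ---------------------------------------------------------------------------
# Ward clustering


def brute_force_ward(X):
    """Naive Ward.D2 agglomeration: merge the pair minimizing the increase
    in total within-cluster variance; returns the merge sequence as sets."""
    clusters = {i: [i] for i in range(len(X))}
    d2 = squareform(pdist(X)) ** 2
    merges = []

    def cost(a, b):
        na, nb = len(clusters[a]), len(clusters[b])
        ca = X[clusters[a]].mean(axis=0)
        cb = X[clusters[b]].mean(axis=0)
        return na * nb / (na + nb) * np.sum((ca - cb) ** 2)

    next_id = len(X)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((cost(a, b), a, b) for i, a in enumerate(keys) for b in keys[i + 1:]),
            key=lambda t: t[0],
        )
        _, a, b = best
        merges.append(frozenset(clusters[a]) | frozenset(clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def scipy_merge_sets(X):
    from scipy.cluster import hierarchy

    Z = hierarchy.linkage(pdist(X), method="ward")
    members = {i: {i} for i in range(len(X))}
    merges = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[len(X) + k] = merged
        merges.append(frozenset(merged))
    return merges


def test_separated_groups_split():
    df = pd.DataFrame({"v": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
    lab = ward_cluster(df, k=2)
    assert lab["a"] == lab["b"] != lab["c"]
    assert lab["c"] == lab["d"]


def test_partition_invariant_to_input_order():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.uniform(size=(12, 2)), index=[f"s{i}" for i in range(12)])
    lab1 = ward_cluster(df, k=3)
    perm = df.sample(frac=1.0, random_state=1)
    lab2 = ward_cluster(perm, k=3)
    part1 = {frozenset(lab1.index[lab1 == c]) for c in lab1.unique()}
    part2 = {frozenset(lab2.index[lab2 == c]) for c in lab2.unique()}
    assert part1 == part2


def test_merge_sequence_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    X = rng.uniform(size=(6, 2))
    assert scipy_merge_sets(X) == brute_force_ward(X)


def test_ward_argument_validation():
    df = pd.DataFrame({"v": [0.0, 1.0]})
    with pytest.raises(ValidationError):
        ward_cluster(df, k=1)
    with pytest.raises(ValidationError):
        ward_cluster(df, k=3)


# ---------------------------------------------------------------------------
# exclusion rule


def fraction_table(caf_values, converged=None):
    idx = [f"s{i}" for i in range(len(caf_values))]
    df = pd.DataFrame({"CAFs": caf_values}, index=idx)
    df[OTHER] = 1.0 - df["CAFs"]
    conv = pd.Series(True if converged is None else converged, index=idx)
    return CellFractionTable(df, converged=conv, fit_residual=pd.Series(0.0, index=idx))


def test_high_caf_cluster_excluded():
    frac = fraction_table([0.62, 0.58, 0.60, 0.22, 0.18, 0.20])
    lab = pd.Series([1, 1, 1, 2, 2, 2], index=frac.sample_ids)
    excluded = exclude_high_fraction_cluster(lab, frac.fractions, threshold=0.483)
    assert excluded == ["s0", "s1", "s2"]


def test_no_cluster_reaches_threshold():
    frac = fraction_table([0.30, 0.28, 0.22, 0.18])
    lab = pd.Series([1, 1, 2, 2], index=frac.sample_ids)
    assert exclude_high_fraction_cluster(lab, frac.fractions) == []


def test_zero_threshold_excludes_everything():
    frac = fraction_table([0.1, 0.2, 0.3, 0.4])
    lab = pd.Series([1, 1, 2, 2], index=frac.sample_ids)
    excluded = exclude_high_fraction_cluster(lab, frac.fractions, threshold=0.0)
    assert excluded == sorted(frac.sample_ids)


# ---------------------------------------------------------------------------
# full refinement


def run_refinement(seed, caf_signature_strength):
    from pemtscope.simulate import SimulationConfig

    cfg = SimulationConfig(
        n_samples=150, n_genes=800, caf_signature_strength=caf_signature_strength, seed=seed
    )
    expr, _, truth = simulate_cohort(cfg)
    gs = GeneSet("sig", signature_genes(cfg))
    scores = score_cohort(expr, gs)
    fractions = deconvolve_cohort(expr, make_reference_profiles(cfg))
    report, retained_expr, rescored = refine_cohort(expr, scores, fractions, gs)
    return report


def test_contaminated_cohort_rho_drops():
    report = run_refinement(seed=12, caf_signature_strength=4.0)
    pre = report.spearman_before.loc["CAFs", "rho"]
    post = report.spearman_after.loc["CAFs", "rho"]
    assert pre > 0
    assert abs(post) < abs(pre)
    assert len(report.excluded_samples) > 0


def test_uncontaminated_cohort_keeps_everyone():
    report = run_refinement(seed=12, caf_signature_strength=0.0)
    assert report.excluded_samples == []


def test_retained_excluded_nonconverged_partition_samples(contaminated_cohort):
    cfg, expr, clinical, truth, gs = contaminated_cohort
    scores = score_cohort(expr, gs)
    fractions = deconvolve_cohort(expr, make_reference_profiles(cfg))
    # force one sample non-converged
    fractions.converged.iloc[0] = False
    forced = fractions.converged.index[0]
    report, retained_expr, rescored = refine_cohort(expr, scores, fractions, gs)
    all_ids = set(expr.sample_ids)
    parts = [
        set(report.retained_samples),
        set(report.excluded_samples),
        set(report.non_converged_samples),
    ]
    assert set().union(*parts) == all_ids
    assert sum(len(p) for p in parts) == len(all_ids)
    assert forced in report.non_converged_samples
    assert forced not in report.retained_samples
    # rescoring covers exactly the retained samples
    assert rescored.sample_ids == report.retained_samples
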