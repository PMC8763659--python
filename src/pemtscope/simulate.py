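"""Synthetic bulk-tumor cohorts with ground truth.

The generator emulates the statistical structure the pEMT pipeline
assumes in a head-and-neck carcinoma cohort:

* per-sample cell-type fractions (tumor, CAFs, immune, endothelial) drawn
  from a Dirichlet whose concentrations reflect highly variable stromal
  content, including fibrotic CAF-dominant samples;
* a latent per-sample pEMT activity (standard normal) that up-regulates
  the signature genes in tumor cells by ``exp(activity_effect * activity)``;
* constitutive signature-gene expression in CAFs scaled by
  ``caf_signature_strength`` — the contamination the refinement step
  removes;
* multiplicative log-normal measurement noise;
* exponential survival whose log-hazard is proportional to activity, with
  independent exponential censoring calibrated to the requested rate.

All randomness flows from one seed through named substreams (profiles,
fractions, activity, noise, survival), so perturbing one component leaves
the others fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, ReferenceProfile, ValidationError

TUMOR = "tumor"
CAF = "CAFs"

#: Dirichlet concentrations for the default four-compartment mixture
DEFAULT_CELL_TYPES: dict[str, float] = {
    TUMOR: 3.0,
    CAF: 1.2,
    "immune": 1.2,
    "endothelial": 0.6,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``activity_effect`` is the log-fold effect of one unit of latent pEMT
    activity on signature genes in tumor cells; ``hazard_log_hr`` the log
    hazard ratio per unit activity; ``baseline_hazard`` is in events per
    month; ``censor_rate`` the expected fraction of censored samples;
    ``noise_sd`` the SD of the multiplicative log-normal noise on the
    natural-log scale.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_signature_genes: int = 15
    cell_types: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    fibrotic_fraction: float | None = None
    fibrotic_caf_concentration: float = 14.0
    caf_signature_strength: float = 0.0
    activity_effect: float = 1.0
    hazard_log_hr: float = float(np.log(2.0))
    baseline_hazard: float = 0.02
    censor_rate: float = 0.3
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_signature_genes <= 0:
            raise ValidationError("all counts must be positive")
        if self.n_signature_genes >= self.n_genes:
            raise ValidationError("signature must be smaller than the gene universe")
        if not self.cell_types or any(a <= 0 for a in self.cell_types.values()):
            raise ValidationError("Dirichlet concentrations must be positive")
        if TUMOR not in self.cell_types:
            raise ValidationError(f"cell_types must include {TUMOR!r}")
        if self.caf_signature_strength < 0:
            raise ValidationError("caf_signature_strength must be >= 0")
        if self.fibrotic_fraction is None:
            # a desmoplastic subgroup accompanies CAF signature contamination:
            # cohorts whose CAFs express the signature are modelled as also
            # containing CAF-dominant (fibrotic) tumors
            self.fibrotic_fraction = 0.2 if self.caf_signature_strength > 1 else 0.0
        if not 0 <= self.fibrotic_fraction < 1:
            raise ValidationError("fibrotic_fraction must be in [0, 1)")
        if self.fibrotic_caf_concentration <= 0:
            raise ValidationError("fibrotic_caf_concentration must be > 0")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if not 0 < self.censor_rate < 1:
            raise ValidationError("censor_rate must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    activity: pd.Series  # latent pEMT activity per sample
    seed: int

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < 0).any():
            raise ValidationError("true fractions must be nonnegative")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("true fractions must sum to 1 per sample")

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["activity"] = self.activity
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def _rng(config: SimulationConfig, substream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[substream]]))


_STREAMS = {"profiles": 0, "fractions": 1, "activity": 2, "noise": 3, "survival": 4}

_SIGNATURE_PREFIX = "SIG"
_BACKGROUND_PREFIX = "G"


def gene_names(config: SimulationConfig) -> list[str]:
    """Signature genes SIG000.., then background genes G000..."""
    m = config.n_signature_genes
    sig = [f"{_SIGNATURE_PREFIX}{i:03d}" for i in range(m)]
    bg = [f"{_BACKGROUND_PREFIX}{i:05d}" for i in range(config.n_genes - m)]
    return sig + bg


def signature_genes(config: SimulationConfig) -> list[str]:
    return gene_names(config)[: config.n_signature_genes]


def make_reference_profiles(config: SimulationConfig) -> ReferenceProfile:
    """Reference expression of deconvolution genes for non-tumor cell types.

    Profiles cover a dedicated block of deconvolution marker genes that
    are unexpressed in the tumor/"other" compartment — the identifiability
    contract that lets the remainder be attributed to "otherCells".
    Deterministic for a fixed seed.
    """
    cell_types = [c for c in config.cell_types if c != TUMOR]
    if not cell_types:
        raise ValidationError("no non-tumor cell types to build reference profiles for")
    n_deconv = min(10 * len(cell_types), config.n_genes - config.n_signature_genes)
    if n_deconv < len(cell_types):
        raise ValidationError(
            f"underdetermined: {n_deconv} deconvolution gene(s) for {len(cell_types)} cell types"
        )
    rng = _rng(config, "profiles")
    genes = [f"D{i:03d}" for i in range(n_deconv)]
    # block-diagonal-ish markers: each type gets a subset of strongly
    # expressed genes plus weak cross-type background
    base = rng.uniform(0.0, 2.0, size=(n_deconv, len(cell_types)))
    for j in range(len(cell_types)):
        block = np.arange(j, n_deconv, len(cell_types))
        base[block, j] += rng.uniform(20.0, 60.0, size=block.size)
    values = pd.DataFrame(base, index=genes, columns=cell_types)
    return ReferenceProfile(values)


def _profile_matrix(config: SimulationConfig, ref: ReferenceProfile | None) -> pd.DataFrame:
    """Full genes x cell-types linear profiles, tumor column included."""
    rng2 = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    genes = gene_names(config)
    cell_types = list(config.cell_types)
    profiles = pd.DataFrame(
        rng2.lognormal(mean=2.0, sigma=1.0, size=(len(genes), len(cell_types))),
        index=genes,
        columns=cell_types,
    )
    if ref is not None:
        # deconvolution marker genes replace their rows with the reference;
        # the tumor/"other" compartment is silent on them
        profiles = pd.concat([profiles, ref.values.reindex(columns=cell_types, fill_value=0.0)])
        profiles = profiles.loc[~profiles.index.duplicated(keep="last")]
        profiles.loc[ref.values.index, TUMOR] = 0.0
    # signature genes: expressed in tumor; constitutive in CAFs scaled by
    # caf_signature_strength; silent in the remaining types
    sig = signature_genes(config)
    base_sig = rng2.uniform(20.0, 60.0, size=len(sig))
    for c in cell_types:
        profiles.loc[sig, c] = 0.0
    profiles.loc[sig, TUMOR] = base_sig
    if CAF in cell_types:
        profiles.loc[sig, CAF] = config.caf_signature_strength * base_sig
    return profiles


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Simulate bulk expression, survival and ground truth.

    Bulk expression is the fraction-weighted mixture of cell-type
    profiles, with tumor-cell signature expression scaled by
    ``exp(activity_effect * activity)``, then multiplied by log-normal
    noise. Survival is exponential with hazard
    ``baseline_hazard * exp(hazard_log_hr * activity)`` and independent
    exponential censoring calibrated so the expected censored fraction is
    ``censor_rate``.
    """
    ref = None
    if len(config.cell_types) > 1:
        ref = make_reference_profiles(config)
    profiles = _profile_matrix(config, ref)
    cell_types = list(config.cell_types)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    frac_rng = _rng(config, "fractions")
    alpha = np.array([config.cell_types[c] for c in cell_types])
    fractions = frac_rng.dirichlet(alpha, size=config.n_samples)
    if config.fibrotic_fraction > 0 and CAF in cell_types:
        fibrotic = frac_rng.random(config.n_samples) < config.fibrotic_fraction
        alpha_fib = alpha.copy()
        alpha_fib[cell_types.index(CAF)] = config.fibrotic_caf_concentration
        fractions[fibrotic] = frac_rng.dirichlet(alpha_fib, size=int(fibrotic.sum()))
    frac_df = pd.DataFrame(fractions, index=samples, columns=cell_types)

    act_rng = _rng(config, "activity")
    activity = pd.Series(act_rng.standard_normal(config.n_samples), index=samples, name="activity")

    sig = signature_genes(config)
    prof = profiles.to_numpy()  # genes x cell types
    bulk = fractions @ prof.T  # samples x genes
    bulk = pd.DataFrame(bulk.T, index=profiles.index, columns=samples)
    # activity modulates only the tumor-cell signature contribution
    sig_idx = profiles.index.get_indexer(sig)
    tumor_col = cell_types.index(TUMOR)
    tumor_sig = np.outer(profiles.loc[sig, TUMOR].to_numpy(), fractions[:, tumor_col])
    boost = np.exp(config.activity_effect * activity.to_numpy())  # per sample
    bulk.iloc[sig_idx, :] += tumor_sig * (boost[None, :] - 1.0)

    if config.noise_sd > 0:
        noise_rng = _rng(config, "noise")
        noise = noise_rng.lognormal(mean=0.0, sigma=config.noise_sd, size=bulk.shape)
        bulk = bulk * noise
    expr = ExpressionMatrix(bulk, scale="linear")

    surv_rng = _rng(config, "survival")
    hazard = config.baseline_hazard * np.exp(config.hazard_log_hr * activity.to_numpy())
    event_time = surv_rng.exponential(1.0 / hazard)
    # exponential censoring with rate c solves E[censored] = c/(c+h) per
    # sample; calibrate c so the cohort-average censored fraction matches
    censor_rate_param = _calibrate_censoring(hazard, config.censor_rate)
    censor_time = surv_rng.exponential(1.0 / censor_rate_param, size=config.n_samples)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)
    clinical = ClinicalTable(
        pd.DataFrame({"time": time, "event": event}, index=samples)
    )
    truth = SyntheticTruth(fractions=frac_df, activity=activity, seed=config.seed)
    return expr, clinical, truth


def _calibrate_censoring(hazard: np.ndarray, target: float) -> float:
    """Censoring rate c with mean_i c / (c + h_i) = target (bisection)."""
    lo, hi = 1e-12, float(hazard.max()) * 1e6 + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(mid / (mid + hazard)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
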