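"""Synthetic cohorts with the statistical structure the analysis assumes.

Each sample carries a latent ferroptosis activity f ~ Normal(0, 1).
Log-scale expression is

    x_gs = baseline_mean + beta_g * f_s + eps_gs,   eps ~ Normal(0, noise_sd^2)

with loading beta_g = +effect_b for driver genes, -effect_b for suppressor
genes, +/-effect_c for planted RFL-correlated genes and 0 for background
genes.  Survival is exponential with hazard

    h_s = baseline_hazard * exp(-hazard_gamma * f_s)

so a positive ``hazard_gamma`` makes high ferroptosis activity favorable
(the direction the score is designed to detect).  Censoring is exponential
and independent of f, with its rate solved so the expected censored
fraction matches ``censor_rate``.  A treated-vs-control design shifts the
latent activity by ``treatment_delta`` in the treated arm, emulating a
ferroptosis inducer (positive shift) or inhibitor (negative shift).

The population Pearson correlation between a gene with loading c and f is
c / sqrt(c^2 + noise_sd^2); the default effect_c is set so planted
correlates have true r ~= 0.5.

All generators are pure functions of (params, seed): one global seed feeds
a hierarchical stream so each stage's draws are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geneset import GeneSet, GeneSetPair

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_treatment_experiment",
    "generate_single_cell",
]


@dataclass(frozen=True)
class SimParams:
    """Reference study conditions for the synthetic cohorts.

    Counts partition the gene universe; effect sizes are loadings on the
    latent activity (log-expression units per SD of f).  ``hazard_gamma``
    is the negative log-hazard slope on f (positive value = high
    ferroptosis favorable); ``baseline_hazard`` is in events per time unit
    (days); ``censor_rate`` the expected censored fraction.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_drivers: int = 40
    n_suppressors: int = 40
    n_planted_pos: int = 30
    n_planted_neg: int = 30
    effect_b: float = 1.0
    effect_c: float = 0.29  # true r = c/sqrt(c^2+sd^2) ~= 0.5 at noise_sd 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_gene_sd: float = 1.0   # spread of per-gene baselines
    signature_boost: float = 4.0    # extra baseline for driver/suppressor genes
    hazard_gamma: float = 0.8
    baseline_hazard: float = 0.002
    censor_rate: float = 0.3
    treatment_delta: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_drivers, self.n_suppressors,
                  self.n_planted_pos, self.n_planted_neg)
        if any(c < 0 for c in counts) or self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("counts must be non-negative, sizes positive")
        if sum(counts) > self.n_genes:
            raise ValueError("special genes exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for recovery tests."""

    latent: pd.Series                 # f per sample (or per patient)
    roles: pd.Series                  # gene -> driver/suppressor/planted_pos/planted_neg/background
    loadings: pd.Series               # gene -> beta_g
    hazard_gamma: float
    baseline_hazard: float
    censor_rate: float
    arm: pd.Series | None = None      # treated/control labels, when applicable


class SyntheticCohort(NamedTuple):
    expression: pd.DataFrame          # genes x samples, log scale
    clinical: pd.DataFrame            # index sample; time, event, age, gender
    pair: GeneSetPair
    truth: SyntheticTruth


def _gene_labels(params: SimParams) -> tuple[pd.Series, pd.Series]:
    """Deterministic gene ids, roles and loadings."""
    ids, roles, loadings = [], [], []
    spec = [
        ("DRV", params.n_drivers, "driver", params.effect_b),
        ("SUP", params.n_suppressors, "suppressor", -params.effect_b),
        ("POS", params.n_planted_pos, "planted_pos", params.effect_c),
        ("NEG", params.n_planted_neg, "planted_neg", -params.effect_c),
    ]
    for prefix, n, role, beta in spec:
        for i in range(n):
            ids.append(f"{prefix}{i:04d}")
            roles.append(role)
            loadings.append(beta)
    n_bg = params.n_genes - len(ids)
    for i in range(n_bg):
        ids.append(f"BG{i:05d}")
        roles.append("background")
        loadings.append(0.0)
    idx = pd.Index(ids, name="gene")
    return pd.Series(roles, index=idx), pd.Series(loadings, index=idx, dtype=float)


def _gene_baselines(
    roles: pd.Series, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene baseline log-expression.

    Signature (driver/suppressor) genes get a positive offset so their
    enrichment scores stay positive across samples, as for expressed
    signatures in real transcriptomes; all genes get an independent
    baseline spread so ranks are not driven by the latent activity alone.
    """
    base = params.baseline_mean + rng.normal(
        0.0, params.baseline_gene_sd, size=len(roles)
    )
    in_signature = roles.isin(["driver", "suppressor"]).to_numpy()
    return base + params.signature_boost * in_signature


def _expression(
    f: np.ndarray, baselines: np.ndarray, loadings: pd.Series, params: SimParams,
    rng: np.random.Generator, sample_ids: list[str],
) -> pd.DataFrame:
    beta = loadings.to_numpy()[:, None]
    noise = rng.normal(0.0, params.noise_sd, size=(len(loadings), f.size))
    values = baselines[:, None] + beta * f[None, :] + noise
    return pd.DataFrame(values, index=loadings.index, columns=sample_ids)


def _pair_from_roles(roles: pd.Series) -> GeneSetPair:
    drivers = frozenset(roles.index[roles == "driver"])
    suppressors = frozenset(roles.index[roles == "suppressor"])
    return GeneSetPair(
        drivers=GeneSet("ferroptosis_drivers", drivers),
        suppressors=GeneSet("ferroptosis_suppressors", suppressors),
    )


def _censoring_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Solve for the exponential censoring rate c with
    mean_s[c / (c + h_s)] = censor_rate."""
    if censor_rate == 0:
        return 0.0

    def gap(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - censor_rate

    lo, hi = 1e-12, float(hazards.max())
    while gap(hi) < 0:
        hi *= 10
    return float(brentq(gap, lo, hi))


def generate_cohort(params: SimParams) -> SyntheticCohort:
    """One bulk cohort: expression, survival, signature pair, ground truth."""
    ss = np.random.SeedSequence(params.seed)
    rng_g, rng_f, rng_x, rng_t, rng_c, rng_cov = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    roles, loadings = _gene_labels(params)
    baselines = _gene_baselines(roles, params, rng_g)
    sample_ids = [f"S{i:04d}" for i in range(params.n_samples)]

    f = rng_f.normal(0.0, 1.0, size=params.n_samples)
    expression = _expression(f, baselines, loadings, params, rng_x, sample_ids)

    hazards = params.baseline_hazard * np.exp(-params.hazard_gamma * f)
    event_times = rng_t.exponential(1.0 / hazards)
    c_rate = _censoring_rate(hazards, params.censor_rate)
    if c_rate > 0:
        censor_times = rng_c.exponential(1.0 / c_rate, size=params.n_samples)
    else:
        censor_times = np.full(params.n_samples, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": rng_cov.normal(60.0, 10.0, size=params.n_samples),
            "gender": np.where(
                rng_cov.random(params.n_samples) < 0.5, "female", "male"
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        latent=pd.Series(f, index=sample_ids, name="latent"),
        roles=roles,
        loadings=loadings,
        hazard_gamma=params.hazard_gamma,
        baseline_hazard=params.baseline_hazard,
        censor_rate=params.censor_rate,
    )
    return SyntheticCohort(expression, clinical, _pair_from_roles(roles), truth)


def generate_treatment_experiment(
    params: SimParams, n_per_arm: int = 20
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Treated-vs-control design: the treated arm's latent activity is
    shifted by ``treatment_delta`` (positive = inducer-like, negative =
    inhibitor-like)."""
    if n_per_arm < 3:
        raise ValueError("need >=3 samples per arm")
    ss = np.random.SeedSequence(params.seed)
    rng_g, rng_f, rng_x = (np.random.default_rng(s) for s in ss.spawn(3))
    roles, loadings = _gene_labels(params)
    baselines = _gene_baselines(roles, params, rng_g)

    f_control = rng_f.normal(0.0, 1.0, size=n_per_arm)
    f_treated = rng_f.normal(params.treatment_delta, 1.0, size=n_per_arm)
    f = np.concatenate([f_control, f_treated])
    sample_ids = [f"CTRL{i:03d}" for i in range(n_per_arm)] + [
        f"TRT{i:03d}" for i in range(n_per_arm)
    ]
    arm = pd.Series(
        ["control"] * n_per_arm + ["treated"] * n_per_arm,
        index=sample_ids, name="arm",
    )
    expression = _expression(f, baselines, loadings, params, rng_x, sample_ids)
    truth = SyntheticTruth(
        latent=pd.Series(f, index=sample_ids, name="latent"),
        roles=roles,
        loadings=loadings,
        hazard_gamma=params.hazard_gamma,
        baseline_hazard=params.baseline_hazard,
        censor_rate=0.0,
        arm=arm,
    )
    return expression, arm, truth


def generate_single_cell(
    params: SimParams, n_patients: int = 5, cells_per_patient: int = 50
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Single-cell data for pseudobulk tests.

    Each patient has a latent activity f_p; each cell's expression is the
    patient log-mean profile plus cell-level Normal noise.  Returns a
    cells x genes matrix, the cell -> patient map, and patient-level truth.
    """
    if cells_per_patient < 1:
        raise ValueError("cells_per_patient must be >= 1")
    ss = np.random.SeedSequence(params.seed)
    rng_g, rng_f, rng_x = (np.random.default_rng(s) for s in ss.spawn(3))
    roles, loadings = _gene_labels(params)
    baselines = _gene_baselines(roles, params, rng_g)
    beta = loadings.to_numpy()

    f_p = rng_f.normal(0.0, 1.0, size=n_patients)
    patient_ids = [f"P{i:03d}" for i in range(n_patients)]

    cell_rows, cell_ids, owners = [], [], []
    for p, pid in enumerate(patient_ids):
        mean_profile = baselines + beta * f_p[p]
        noise = rng_x.normal(
            0.0, params.noise_sd, size=(cells_per_patient, len(beta))
        )
        cell_rows.append(mean_profile[None, :] + noise)
        cell_ids.extend(f"{pid}_C{j:04d}" for j in range(cells_per_patient))
        owners.extend([pid] * cells_per_patient)

    cells = pd.DataFrame(
        np.vstack(cell_rows), index=pd.Index(cell_ids, name="cell"),
        columns=loadings.index,
    )
    mapping = pd.Series(owners, index=cells.index, name="patient")
    truth = SyntheticTruth(
        latent=pd.Series(f_p, index=patient_ids, name="latent"),
        roles=roles,
        loadings=loadings,
        hazard_gamma=params.hazard_gamma,
        baseline_hazard=params.baseline_hazard,
        censor_rate=0.0,
    )
    return cells, mapping, truth


def with_seed(params: SimParams, seed: int) -> SimParams:
    """Convenience: same conditions, different stream."""
    return replace(params, seed=seed)
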