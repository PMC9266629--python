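"""Survival analysis: Kaplan–Meier, log-rank, min-P cutoff scan, Cox, ROC.

The stratification procedure scans every distinct observed RFL value inside
the 10th–90th percentile window as a candidate cutoff, runs a two-group
log-rank test for each, and keeps the cutoff with the smallest P.  The
minimum-P scan is reported as-is for fidelity with common practice, but it
inflates type I error; an optional permutation adjustment of the selected P
is provided (off by default) for honest inference.

Kaplan–Meier, log-rank and Cox partial-likelihood fits (Breslow tie
handling) are delegated to lifelines; the risk score is the Cox linear
predictor centered at the fitting-cohort covariate means, so RS > 0 means
above-average modeled risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


def _check_records(records: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records missing column {col!r}")
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a DataFrame with columns ``time`` and
    ``survival`` (one row per distinct observed time, survival evaluated
    just after that time).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided P).

    Uses the hypergeometric variance at each distinct event time; P from
    the chi-square distribution with 1 df.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    _check_records(group_a)
    _check_records(group_b)
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CutoffScanResult:
    """Outcome of the percentile-window min-P cutoff scan."""

    best_cutoff: float
    best_p: float
    hazard_ratio: float
    scanned: pd.DataFrame  # columns: cutoff, p, n_high, n_low
    permutation_p: float | None = None


def scan_cutoff(
    rfl: pd.Series,
    records: pd.DataFrame,
    lo: float = 0.10,
    hi: float = 0.90,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutoffScanResult:
    """Pick the RFL cutoff minimizing the two-group log-rank P.

    Candidate cutoffs are every distinct observed RFL value between the
    ``lo`` and ``hi`` quantiles (linear-interpolation definition) that
    leaves both groups (rfl > cutoff vs rfl <= cutoff) non-empty.  Ties on
    the minimum P are broken toward the cutoff closest to the median RFL.
    The hazard ratio (high vs low) comes from a univariate Cox fit at the
    selected cutoff.

    With ``n_permutations`` > 0, a permutation-adjusted P for the selected
    minimum (re-scanning under label permutation) is also reported; the
    unadjusted minimum remains the headline value.
    """
    joined = pd.concat([rfl.rename("rfl"), records], axis=1, join="inner").dropna(
        subset=["rfl"]
    )
    if len(joined) < 10:
        raise ValueError("need >=10 samples with defined RFL")
    _check_records(joined)
    if joined["event"].sum() == 0:
        raise ValueError("no events observed")
    values = joined["rfl"].to_numpy(dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("RFL is constant; no cutoff stratifies the cohort")

    def _scan(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
        q_lo, q_hi = np.quantile(values, [lo, hi])
        vmin, vmax = values.min(), values.max()
        candidates = [
            v for v in np.unique(values)
            if q_lo <= v <= q_hi and vmin < v < vmax
        ]
        rows = []
        for v in candidates:
            high = values > v
            if high.sum() == 0 or (~high).sum() == 0:
                continue
            if events[high].sum() + events[~high].sum() == 0:
                continue
            res = _ll_logrank(
                times[high], times[~high],
                event_observed_A=events[high], event_observed_B=events[~high],
            )
            rows.append((float(v), float(res.p_value), int(high.sum()),
                         int((~high).sum())))
        return pd.DataFrame(rows, columns=["cutoff", "p", "n_high", "n_low"])

    times = joined["time"].to_numpy(dtype=float)
    events = joined["event"].to_numpy(dtype=int)
    scanned = _scan(times, events)
    if scanned.empty:
        raise ValueError("no candidate cutoff yields two testable groups")

    best_p = float(scanned["p"].min())
    at_min = scanned[np.isclose(scanned["p"], best_p)]
    median = float(np.median(values))
    best_cutoff = float(
        at_min.loc[(at_min["cutoff"] - median).abs().idxmin(), "cutoff"]
    )

    cox_df = pd.DataFrame(
        {"time": times, "event": events, "high": (values > best_cutoff).astype(int)}
    )
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = cox_fit(cox_df, covariates=["high"])
    except ConvergenceError:
        # monotone likelihood (e.g. one group nearly event-free at an extreme
        # cutoff); a small ridge penalty keeps the HR estimate finite
        logger.warning("univariate Cox at best cutoff did not converge; "
                       "refitting with ridge penalty 0.1")
        fit = cox_fit(cox_df, covariates=["high"], penalizer=0.1)
    hr = float(fit.hazard_ratios["high"])

    perm_p: float | None = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(times))
            perm_min = _scan(times[perm], events[perm])["p"].min()
            if perm_min <= best_p:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)

    return CutoffScanResult(
        best_cutoff=best_cutoff, best_p=best_p, hazard_ratio=hr,
        scanned=scanned, permutation_p=perm_p,
    )


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    p_values: pd.Series
    covariate_centers: pd.Series
    dropped: list[str] = field(default_factory=list)
    design_columns: list[str] = field(default_factory=list)

    def classify(self, alpha: float = 0.05) -> pd.Series:
        """Per-covariate call: poor (HR>1, P<alpha), favorable (HR<1,
        P<alpha) or ns."""
        calls = pd.Series("ns", index=self.coefficients.index, dtype=object)
        sig = self.p_values < alpha
        calls[sig & (self.hazard_ratios > 1)] = "poor"
        calls[sig & (self.hazard_ratios < 1)] = "favorable"
        return calls


def _one_hot(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Design matrix: numeric covariates as-is, categoricals one-hot against
    the first (sorted) level as reference."""
    cols: dict[str, pd.Series] = {}
    for cov in covariates:
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols[f"{cov}_{level}"] = (col.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=records.index)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    penalizer: float = 0.0,
) -> CoxResult:
    """Fit a Cox proportional-hazards model (Breslow tie handling).

    ``records`` carries ``time``, ``event`` and covariate columns; when
    ``covariates`` is None every extra column is used.  Categorical
    covariates are one-hot encoded against a reference level; constant
    columns are dropped with a warning; at least 2 events are required.
    ``penalizer`` adds an L2 penalty on the coefficients — useful for
    collinear multi-gene panels; leave at 0 for inference.
    """
    _check_records(records)
    if covariates is None:
        covariates = [c for c in records.columns if c not in ("time", "event")]
    if not covariates:
        raise ValueError("no covariates to fit")
    if records["event"].sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    if records[covariates].isna().any().any():
        bad = records.index[records[covariates].isna().any(axis=1)]
        raise ValueError(f"missing covariate values for samples {list(bad[:5])}")

    design = _one_hot(records, covariates)
    dropped = [c for c in design.columns if design[c].nunique() < 2]
    if dropped:
        warnings.warn(
            f"dropping constant covariates: {dropped}", UserWarning, stacklevel=2
        )
        design = design.drop(columns=dropped)
    if design.shape[1] == 0:
        raise ValueError("all covariates constant; nothing to fit")

    df = pd.concat(
        [records[["time", "event"]].astype(float), design], axis=1
    )
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    return CoxResult(
        coefficients=summary["coef"].rename("coef"),
        hazard_ratios=summary["exp(coef)"].rename("hr"),
        p_values=summary["p"].rename("p"),
        covariate_centers=design.mean().rename("center"),
        dropped=dropped,
        design_columns=list(design.columns),
    )


@dataclass
class RiskModel:
    """Centered Cox linear predictor (risk score) and RS>0 / RS<0 groups."""

    coefficients: pd.Series
    covariate_centers: pd.Series
    risk_score: pd.Series
    group: pd.Series  # "high" (RS > 0) vs "low"


def risk_score(model: CoxResult, covariate_matrix: pd.DataFrame) -> RiskModel:
    """Score samples with a fitted Cox model.

    RS = sum_k beta_k (z_k - center_k) with centers the fitting-cohort
    covariate means, so the fitting cohort has mean RS 0 and RS > 0 reads
    as above-average modeled risk.
    """
    missing_cols = [c for c in model.design_columns if c not in covariate_matrix]
    if missing_cols:
        raise ValueError(f"covariate matrix missing columns {missing_cols}")
    X = covariate_matrix[model.design_columns]
    if X.isna().any().any():
        bad = X.index[X.isna().any(axis=1)]
        raise ValueError(f"missing covariate values for samples {list(bad[:5])}")
    centered = X - model.covariate_centers[model.design_columns]
    rs = centered.mul(model.coefficients[model.design_columns]).sum(axis=1)
    rs.name = "risk_score"
    group = pd.Series(
        np.where(rs > 0, "high", "low"), index=rs.index, name="group"
    )
    return RiskModel(
        coefficients=model.coefficients,
        covariate_centers=model.covariate_centers,
        risk_score=rs,
        group=group,
    )


def roc_auc(score: pd.Series | np.ndarray, outcome: pd.Series | np.ndarray) -> float:
    """AUC: probability a random event sample outscores a random non-event
    sample, ties counting one half."""
    outcome = np.asarray(outcome)
    score = np.asarray(score, dtype=float)
    classes = np.unique(outcome)
    if classes.size != 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(outcome, score))
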