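"""Relative ferroptosis level (RFL): construction, validation and grouping.

RFL is the per-sample ratio of two ssGSEA activities,

    RFL = drive activity / suppress activity,

where drive activity scores the ferroptosis-driver signature and suppress
activity the suppressor signature.  A raw enrichment score can be zero or
negative; samples whose suppress activity is not strictly positive get an
undefined RFL (NaN) and are excluded from downstream stages with a logged
count.  High RFL is read as a high relative ferroptosis level; in the
cancers where the score validates, high-RFL cases show favorable survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: validation rule: a cohort passes when r(RFL, drive) exceeds +0.2 and
#: r(RFL, suppress) is below -0.2 (cohorts failing this are excluded from
#: survival analyses)
VALIDATION_R = 0.2


def compute_rfl(
    drive: pd.Series, suppress: pd.Series
) -> pd.DataFrame:
    """Build the per-sample activity table with the RFL ratio.

    Returns a DataFrame indexed by sample with columns ``drive_activity``,
    ``suppress_activity``, ``rfl`` (NaN where suppress activity <= 0) and
    ``group`` (unset; see :func:`assign_groups`).
    """
    if not drive.index.equals(suppress.index):
        raise ValueError("drive and suppress vectors must share sample ids")
    suppress_vals = suppress.to_numpy(dtype=float)
    rfl = np.where(suppress_vals > 0, drive.to_numpy(dtype=float) / suppress_vals, np.nan)
    n_undef = int(np.isnan(rfl).sum())
    if n_undef == len(rfl):
        raise ValueError("RFL undefined for every sample (suppress activity <= 0)")
    if n_undef:
        logger.info(
            "RFL undefined for %d of %d samples (non-positive suppress activity)",
            n_undef, len(rfl),
        )
    return pd.DataFrame(
        {
            "drive_activity": drive.astype(float),
            "suppress_activity": suppress.astype(float),
            "rfl": rfl,
            "group": pd.Series(pd.NA, index=drive.index, dtype="string"),
        }
    )


@dataclass(frozen=True)
class RflValidation:
    """Pearson correlations of RFL against its two components."""

    r_drive: float
    p_drive: float
    r_suppress: float
    p_suppress: float

    @property
    def passed(self) -> bool:
        return (
            np.isfinite(self.r_drive)
            and np.isfinite(self.r_suppress)
            and self.r_drive > VALIDATION_R
            and self.r_suppress < -VALIDATION_R
        )


def validate_rfl(table: pd.DataFrame) -> RflValidation:
    """Correlate RFL with drive and suppress activity over defined samples.

    A cohort passes when RFL tracks drive activity positively (r > +0.2)
    and suppress activity negatively (r < -0.2); otherwise the score is not
    a usable ferroptosis read-out in that cohort.  Constant components give
    NaN correlations and a failing result.
    """
    defined = table.dropna(subset=["rfl"])
    if len(defined) < 3:
        raise ValueError("need >=3 samples with defined RFL to validate")

    def _corr(x: pd.Series, y: pd.Series) -> tuple[float, float]:
        if x.nunique() < 2 or y.nunique() < 2:
            return (float("nan"), float("nan"))
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_d, p_d = _corr(defined["rfl"], defined["drive_activity"])
    r_s, p_s = _corr(defined["rfl"], defined["suppress_activity"])
    return RflValidation(r_drive=r_d, p_drive=p_d, r_suppress=r_s, p_suppress=p_s)


def assign_groups(rfl: pd.Series, cutoff: float) -> pd.Series:
    """Label samples ``high`` (rfl > cutoff) or ``low`` (rfl <= cutoff).

    The cutoff must lie strictly inside the observed range of defined RFL so
    both groups are non-empty; undefined RFL yields a missing label.
    """
    defined = rfl.dropna()
    if defined.empty:
        raise ValueError("no defined RFL values")
    lo, hi = float(defined.min()), float(defined.max())
    if not (lo < cutoff < hi):
        raise ValueError(
            f"cutoff {cutoff} outside the open range of RFL ({lo}, {hi}); "
            "would give an empty group"
        )
    labels = pd.Series(pd.NA, index=rfl.index, dtype="string")
    labels[rfl.notna()] = np.where(rfl.dropna() > cutoff, "high", "low")
    return labels


def pseudobulk(
    cell_matrix: pd.DataFrame, cell_to_patient: pd.Series
) -> pd.DataFrame:
    """Average single-cell expression per patient into a pseudobulk matrix.

    ``cell_matrix`` is cells x genes; the result is genes x patients with
    entry (g, p) the arithmetic mean of gene g over the cells of patient p,
    on the values as provided (no re-normalization).

    Raises
    ------
    ValueError
        If any cell lacks a patient assignment.
    """
    mapping = pd.Series(cell_to_patient)
    unmapped = cell_matrix.index.difference(mapping.index)
    if len(unmapped) > 0:
        raise ValueError(
            f"{len(unmapped)} cells have no patient assignment "
            f"(e.g. {list(unmapped[:3])})"
        )
    groups = mapping.reindex(cell_matrix.index)
    profile = cell_matrix.groupby(groups, sort=True).mean()
    return profile.T  # genes x patients


def correlate_rfl_with_features(
    rfl: pd.Series, features: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided P of RFL against each per-sample feature.

    Pairs with a missing value in either vector are dropped per feature;
    constant features are flagged undefined (NaN r and P).  P-values use
    the t distribution with n-2 degrees of freedom.
    """
    out = []
    for name, col in features.items():
        pair = pd.concat([rfl, col], axis=1, keys=["rfl", "feat"]).dropna()
        if len(pair) < 3:
            raise ValueError(f"feature {name!r}: fewer than 3 complete pairs")
        if pair["feat"].nunique() < 2 or pair["rfl"].nunique() < 2:
            out.append((name, np.nan, np.nan, len(pair)))
            continue
        r, p = stats.pearsonr(pair["rfl"], pair["feat"])
        out.append((name, float(r), float(p), len(pair)))
    return pd.DataFrame(out, columns=["feature", "r", "p", "n"]).set_index("feature")
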