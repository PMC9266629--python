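"""Screening for RFL-correlated genes across cohorts.

Per cohort, every gene is Pearson-correlated with the per-sample RFL; genes
with r > +0.3 and P < 0.05 (strict inequalities) are called positive, with
r < -0.3 and P < 0.05 negative.  Genes recurrently called in the same
direction in at least ``min_cohorts`` cohorts — with zero calls in the
opposite direction — are the recurrent RFL-correlated genes.  Jaccard
indices quantify how much two cohorts' correlated-gene sets overlap.

No multiple-testing correction is applied by default, matching the screen's
marginal-threshold design; a Benjamini–Hochberg option is exposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

THRESHOLD_R = 0.3
THRESHOLD_P = 0.05


@dataclass
class ScreenResult:
    """Per-gene correlation screen for one cohort."""

    cohort: str
    table: pd.DataFrame  # index gene; columns r, p, class

    @property
    def positive(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["class"] == "positive"])

    @property
    def negative(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["class"] == "negative"])


def _pearson_vs_vector(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of a genes x samples array against one vector,
    with two-sided P from t = r sqrt(n-2)/sqrt(1-r^2)."""
    n = y.size
    xc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r[denom == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    return r, p


def correlate_genes(
    matrix: pd.DataFrame,
    rfl: pd.Series,
    cohort: str = "cohort",
    threshold_r: float = THRESHOLD_R,
    threshold_p: float = THRESHOLD_P,
    bh_correct: bool = False,
) -> ScreenResult:
    """Pearson-correlate every gene's expression with RFL.

    Samples with undefined RFL are dropped; the matrix (genes x samples)
    must cover the remaining samples.  Constant genes are flagged undefined
    (class ``none``).  With ``bh_correct``, classes are assigned on
    Benjamini–Hochberg adjusted P-values instead of raw ones.
    """
    rfl = rfl.dropna()
    if len(rfl) < 3:
        raise ValueError("need >=3 samples with defined RFL")
    missing = rfl.index.difference(matrix.columns)
    if len(missing) > 0:
        raise ValueError(f"expression matrix lacks samples {list(missing[:5])}")
    sub = matrix[rfl.index]
    r, p = _pearson_vs_vector(sub.to_numpy(dtype=float), rfl.to_numpy(dtype=float))

    p_class = p.copy()
    if bh_correct:
        ok = ~np.isnan(p)
        adj = np.full_like(p, np.nan)
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        p_class = adj

    cls = np.full(len(r), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        cls[(r > threshold_r) & (p_class < threshold_p)] = "positive"
        cls[(r < -threshold_r) & (p_class < threshold_p)] = "negative"
    table = pd.DataFrame({"r": r, "p": p, "class": cls}, index=matrix.index)
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        logger.info("%s: %d constant genes flagged undefined", cohort, n_undef)
    return ScreenResult(cohort=cohort, table=table)


def select_correlated(
    result: ScreenResult,
    threshold_r: float = THRESHOLD_R,
    threshold_p: float = THRESHOLD_P,
) -> tuple[frozenset[str], frozenset[str]]:
    """(positive, negative) gene sets at strict |r| and P thresholds."""
    t = result.table
    with np.errstate(invalid="ignore"):
        pos = t.index[(t["r"] > threshold_r) & (t["p"] < threshold_p)]
        neg = t.index[(t["r"] < -threshold_r) & (t["p"] < threshold_p)]
    return frozenset(pos), frozenset(neg)


def recurrent_genes(
    selections: dict[str, tuple[frozenset[str], frozenset[str]]],
    min_cohorts: int = 7,
) -> pd.DataFrame:
    """Genes consistently correlated with RFL across cohorts.

    A gene is selected when it is called in one direction in at least
    ``min_cohorts`` cohorts and never in the other direction.  Returns a
    DataFrame indexed by gene with columns ``n_positive``, ``n_negative``,
    ``selected`` and ``direction``, sorted by gene id (cohort order is
    irrelevant).
    """
    if len(selections) < min_cohorts:
        raise ValueError(
            f"need at least {min_cohorts} cohorts, got {len(selections)}"
        )
    counts: dict[str, list[int]] = {}
    for pos, neg in selections.values():
        for g in pos:
            counts.setdefault(g, [0, 0])[0] += 1
        for g in neg:
            counts.setdefault(g, [0, 0])[1] += 1
    rows = []
    for g in sorted(counts):
        n_pos, n_neg = counts[g]
        if n_pos >= min_cohorts and n_neg == 0:
            selected, direction = True, "positive"
        elif n_neg >= min_cohorts and n_pos == 0:
            selected, direction = True, "negative"
        else:
            selected, direction = False, "none"
        rows.append((g, n_pos, n_neg, selected, direction))
    return pd.DataFrame(
        rows, columns=["gene", "n_positive", "n_negative", "selected", "direction"]
    ).set_index("gene")


def jaccard_matrix(sets: dict[str, frozenset[str] | set[str]]) -> pd.DataFrame:
    """Symmetric matrix of Jaccard indices J(A,B) = |A∩B| / |A∪B|.

    A pair whose union is empty gets 0 with a warning (both sets empty).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 cohorts")
    names = list(sets)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            union = len(sets[a] | sets[b])
            if union == 0:
                warnings.warn(
                    f"both gene sets empty for pair ({a}, {b}); Jaccard set to 0",
                    UserWarning, stacklevel=2,
                )
                j = 0.0
            else:
                j = len(sets[a] & sets[b]) / union
            mat.loc[a, b] = j
            mat.loc[b, a] = j
    return mat
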