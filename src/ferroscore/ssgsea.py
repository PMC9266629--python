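"""Single-sample gene-set enrichment (ssGSEA) scoring engine.

For one sample, genes are ranked by expression within the sample (ascending
ranks 1..N, average ties).  Walking the genes in order of decreasing rank,
the enrichment score accumulates the difference between the weighted
fraction of set genes encountered so far and the fraction of non-set genes:

    P_in(i)  = sum_{j<=i, g_j in S} r_{g_j}^alpha / sum_{g in S} r_g^alpha
    P_out(i) = #{j<=i, g_j not in S} / (N - |S|)
    ES       = sum_{i=1}^{N} (P_in(i) - P_out(i))

with ``alpha >= 0`` the rank-weighting exponent (0.25 by default, the usual
ssGSEA choice).  The score depends on expression only through within-sample
ranks, so it is invariant to any strictly increasing per-sample transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geneset import GeneSet

logger = logging.getLogger(__name__)

_TIE_METHODS = ("average", "min", "max", "dense", "ordinal")


@dataclass(frozen=True)
class SsgseaParams:
    """Scoring parameters.

    alpha : rank-weighting exponent, >= 0.
    normalize : divide all scores in one call by (max ES - min ES) over the
        whole score table.  Off by default: the drive/suppress ratio is
        invariant to this common positive rescaling, and raw scores keep
        their signs interpretable.
    tie_method : how tied expression values are ranked (default "average").
    """

    alpha: float = 0.25
    normalize: bool = False
    tie_method: str = "average"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.tie_method not in _TIE_METHODS:
            raise ValueError(f"unknown tie_method {self.tie_method!r}")


def rank_transform(column: np.ndarray, tie_method: str = "average") -> np.ndarray:
    """Within-sample ranks in [1, N], ascending with expression."""
    values = np.asarray(column, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D expression vector with at least 2 genes")
    return rankdata(values, method=tie_method)


def _es_kernel(r_sorted: np.ndarray, in_sorted: np.ndarray, alpha: float) -> float:
    """ES from ranks already sorted in walk order with a set-membership mask."""
    n = r_sorted.size
    n_in = int(in_sorted.sum())
    if n_in == 0:
        raise ValueError("no gene of the set is measured in the matrix")
    if n_in == n:
        raise ValueError("gene set covers all measured genes; ES undefined")
    weights = np.where(in_sorted, r_sorted**alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def es_single(
    ranks: np.ndarray,
    gene_ids: np.ndarray,
    gene_set: frozenset[str] | set[str],
    alpha: float = 0.25,
) -> float:
    """Raw enrichment score of one gene set in one ranked sample.

    ``ranks`` and ``gene_ids`` are aligned; genes in ``gene_set`` absent
    from ``gene_ids`` are ignored.  Equal ranks are walked in lexicographic
    gene-id order for determinism.

    Raises
    ------
    ValueError
        If no set gene is measured, or the set covers every measured gene
        (the out-of-set fraction would divide by zero).
    """
    ranks = np.asarray(ranks, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n = ranks.size
    in_set = np.fromiter((g in gene_set for g in gene_ids), bool, count=n)
    # decreasing rank; ties broken by gene id for a deterministic walk
    order = np.lexsort((gene_ids, -ranks))
    return _es_kernel(ranks[order], in_set[order], alpha)


def score_matrix(
    matrix: pd.DataFrame,
    sets: list[GeneSet],
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Score every gene set in every sample of a genes x samples matrix.

    Returns a set x sample DataFrame of enrichment scores.  Set genes absent
    from the matrix are intersected out (logged); a set with no measured
    gene is an error naming the set.
    """
    params = params or SsgseaParams()
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")
    gene_ids = matrix.index.to_numpy(dtype=object)
    measured = set(matrix.index)

    masks: list[np.ndarray] = []
    for gs in sets:
        inter = gs.genes & measured
        if not inter:
            raise ValueError(f"gene set {gs.name!r} has no measured genes")
        dropped = len(gs.genes) - len(inter)
        if dropped:
            logger.info(
                "set %s: %d of %d genes not measured; intersected out",
                gs.name, dropped, len(gs.genes),
            )
        masks.append(
            np.fromiter((g in inter for g in gene_ids), bool, count=len(gene_ids))
        )

    values = matrix.to_numpy(dtype=float)
    scores = np.empty((len(sets), matrix.shape[1]))
    for j in range(matrix.shape[1]):
        ranks = rank_transform(values[:, j], params.tie_method)
        order = np.lexsort((gene_ids, -ranks))
        r_sorted = ranks[order]
        for i, mask in enumerate(masks):
            scores[i, j] = _es_kernel(r_sorted, mask[order], params.alpha)

    table = pd.DataFrame(
        scores, index=[gs.name for gs in sets], columns=matrix.columns
    )
    if params.normalize:
        rng = float(table.max().max() - table.min().min())
        if rng == 0.0:
            raise ValueError("cannot normalize: all scores identical")
        table = table / rng
    return table
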