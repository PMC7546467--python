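"""Bulk-guided refinement of a clustering by stochastic local search.

Bulk bisulfite data give, per CpG, the number of methylated reads out of
a depth D; aggregating the (observed + imputed) single-cell states to
the same scale — methylated-cell fraction times D — yields a residual
score against the bulk counts.  Starting from the best mixture fit, the
search keeps the number of clusters fixed and repeatedly proposes moving
"uncertain" cells (maximum assignment probability below 0.99) to one of
their "candidate" clusters (assignment probability at least 0.01),
re-imputing the cell's missing entries from the destination cluster's
epigenotype.  Score-improving moves are always accepted; worsening moves
are accepted 20% of the time to escape local minima.  After 10 sweeps the
best configuration ever visited is returned.  Only CpGs in regions whose
MAP epigenotypes differ between clusters enter the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import BulkProfile

logger = logging.getLogger(__name__)

__all__ = ["bulk_score", "differentiating_cpgs", "bulk_local_search", "RefinementResult"]


def differentiating_cpgs(
    map_epigenotypes: np.ndarray,
    region_index: np.ndarray,
    clusters: np.ndarray | None = None,
) -> np.ndarray:
    """Columns of regions whose epigenotypes differ between any two clusters.

    ``clusters`` restricts the comparison to the occupied cluster rows.
    """
    G = map_epigenotypes if clusters is None else map_epigenotypes[clusters]
    if len(G) < 2:
        return np.array([], dtype=np.int64)
    varies = (G != G[0]).any(axis=0)  # per-column disagreement
    diff_regions = np.unique(region_index[varies])
    return np.where(np.isin(region_index, diff_regions))[0]


def bulk_score(
    imputed: np.ndarray,
    bulk: BulkProfile,
    cpgs: np.ndarray | None = None,
) -> float:
    """Sum of |D_m * methylated-cell fraction - b_m| over the given CpGs.

    ``imputed`` must be a complete N x M binary matrix; lower is better.
    """
    N = imputed.shape[0]
    if cpgs is None:
        cpgs = np.arange(imputed.shape[1])
    if len(cpgs) == 0:
        logger.warning("bulk_score: empty differentiating-CpG set; score is 0")
        return 0.0
    frac = imputed[:, cpgs].sum(axis=0) / N
    expected = bulk.total[cpgs] * frac
    return float(np.abs(expected - bulk.meth[cpgs]).sum())


@dataclass
class RefinementResult:
    labels: np.ndarray
    imputed: np.ndarray
    score: float
    initial_score: float
    n_iterations: int
    n_proposals: int = 0
    n_worse_proposals: int = 0
    n_worse_accepted: int = 0
    moved_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def worse_acceptance_rate(self) -> float:
        if self.n_worse_proposals == 0:
            return float("nan")
        return self.n_worse_accepted / self.n_worse_proposals


def bulk_local_search(
    results,
    bulk: BulkProfile,
    rng=None,
    n_iterations: int = 10,
    accept_worse_prob: float = 0.2,
    uncertain_threshold: float = 0.99,
    candidate_floor: float = 0.01,
    initial_labels: np.ndarray | None = None,
) -> RefinementResult:
    """Refine a mixture fit's assignments against a bulk profile.

    Parameters
    ----------
    results : BernoulliMixtureResults
        The starting configuration (its MAP labels and unadjusted
        imputation).
    bulk : BulkProfile
        Per-CpG methylated counts at depth D, aligned with the matrix
        columns.
    rng : seed or Generator
    n_iterations : int
        Number of full sweeps over the uncertain cells.
    accept_worse_prob : float
        Probability of keeping a score-worsening reassignment.
    uncertain_threshold, candidate_floor : float
        A cell is uncertain iff its top assignment probability is below
        the threshold; its candidate clusters are those with probability
        at least the floor.
    initial_labels : array, optional
        Start from these raw cluster labels instead of the fit's MAP
        labels (uncertainty and candidates still come from the fit).
    """
    rng = np.random.default_rng(rng)
    model = results.model
    resp = results.resp
    raw_labels = (
        results._raw_labels.copy()
        if initial_labels is None
        else np.asarray(initial_labels, dtype=np.int64).copy()
    )
    start_labels = raw_labels.copy()
    G = results.map_epigenotypes  # K x M in model column order

    # complete matrix in model column order (observed pass through)
    obs1 = model._X1.astype(bool)
    obs0 = model._X0.astype(bool)
    observed = obs1 | obs0
    imputed = np.where(observed, obs1.astype(np.int8), G[raw_labels])

    occupied = np.unique(raw_labels)
    cpgs = differentiating_cpgs(G, model.region_index, clusters=occupied)
    # bulk columns follow the original column order; align to model order
    meth = bulk.meth
    total = bulk.total
    if model._col_order is not None:
        meth = meth[model._col_order]
        total = total[model._col_order]
    bulk_m = BulkProfile(
        chrom=np.array(["."] * model.M, dtype=object),
        pos=np.arange(1, model.M + 1),
        meth=meth,
        total=total,
    )

    init_score = bulk_score(imputed, bulk_m, cpgs)
    uncertain = np.where(resp.max(axis=1) < uncertain_threshold)[0]
    result = RefinementResult(
        labels=raw_labels.copy(),
        imputed=imputed.copy(),
        score=init_score,
        initial_score=init_score,
        n_iterations=n_iterations,
    )
    if len(uncertain) == 0 or len(cpgs) == 0:
        if len(cpgs) == 0:
            logger.warning("bulk refinement: no differentiating regions; no-op")
        result.labels = _relabel(result.labels)
        return result

    candidates = {
        int(n): [int(k) for k in np.where(resp[n] >= candidate_floor)[0]]
        for n in uncertain
    }

    N = model.N
    colsum = imputed[:, cpgs].sum(axis=0).astype(float)
    target_m = bulk_m.meth[cpgs].astype(float)
    target_d = bulk_m.total[cpgs].astype(float)
    cur_score = init_score
    best_score = init_score
    best_labels = raw_labels.copy()
    best_imputed = imputed.copy()
    miss = ~observed

    for _it in range(n_iterations):
        order = rng.permutation(uncertain)
        for n in order:
            cands = [k for k in candidates[int(n)] if k != raw_labels[n]]
            if not cands:
                continue
            k_new = cands[int(rng.integers(len(cands)))]
            new_row = np.where(miss[n], G[k_new], imputed[n])
            delta = new_row[cpgs].astype(float) - imputed[n, cpgs].astype(float)
            new_colsum = colsum + delta
            new_score = float(
                np.abs(target_d * new_colsum / N - target_m).sum()
            )
            result.n_proposals += 1
            if new_score < cur_score:
                accept = True
            else:
                result.n_worse_proposals += 1
                accept = rng.random() < accept_worse_prob
                if accept:
                    result.n_worse_accepted += 1
            if accept:
                raw_labels[n] = k_new
                imputed[n] = new_row
                colsum = new_colsum
                cur_score = new_score
                if cur_score < best_score:
                    best_score = cur_score
                    best_labels = raw_labels.copy()
                    best_imputed = imputed.copy()

    moved = np.where(best_labels != start_labels)[0]
    out_imputed = best_imputed
    if model._col_order is not None:
        inv = np.empty(model.M, dtype=np.int64)
        inv[model._col_order] = np.arange(model.M)
        out_imputed = best_imputed[:, inv]
    return RefinementResult(
        labels=_relabel(best_labels),
        imputed=out_imputed,
        score=best_score,
        initial_score=init_score,
        n_iterations=n_iterations,
        n_proposals=result.n_proposals,
        n_worse_proposals=result.n_worse_proposals,
        n_worse_accepted=result.n_worse_accepted,
        moved_cells=moved,
    )


def _relabel(labels: np.ndarray) -> np.ndarray:
    uniq = list(dict.fromkeys(labels.tolist()))
    remap = {k: i for i, k in enumerate(uniq)}
    return np.array([remap[k] for k in labels], dtype=np.int64)
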