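"""Clustering and imputation performance measures against ground truth.

Implements the V-measure (homogeneity / completeness harmonic mean),
cluster prevalence mean absolute error with optimal cluster matching,
Hamming distance between true and inferred methylation-state vectors,
an uncertainty true-positive rate for ambiguous cells, and the
true x predicted co-clustering percentage table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy


def _contingency(true_labels, pred_labels) -> np.ndarray:
    t = pd.factorize(np.asarray(true_labels))[0]
    p = pd.factorize(np.asarray(pred_labels))[0]
    C = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(C, (t, p), 1)
    return C


def v_measure(true_labels, pred_labels) -> tuple[float, float, float]:
    """Homogeneity h, completeness, and their harmonic mean V.

    ``h = 1 - H(true|pred) / H(true)`` (defined as 1 when the truth is a
    single class) and symmetrically for completeness; ``V = 2hc/(h+c)``
    with V = 0 when both vanish.  Entropies use natural log; the measure
    is invariant to the base.
    """
    true_labels, pred_labels = np.asarray(true_labels), np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label vectors must have equal length")
    n = len(true_labels)
    C = _contingency(true_labels, pred_labels).astype(float)
    pt = C.sum(axis=1) / n
    pp = C.sum(axis=0) / n
    h_true = -xlogy(pt, pt).sum()
    h_pred = -xlogy(pp, pp).sum()
    joint = C / n
    h_joint = -xlogy(joint, joint).sum()
    h_true_given_pred = h_joint - h_pred
    h_pred_given_true = h_joint - h_true
    h = 1.0 if h_true == 0 else 1.0 - h_true_given_pred / h_true
    comp = 1.0 if h_pred == 0 else 1.0 - h_pred_given_true / h_pred
    v = 0.0 if (h + comp) == 0 else 2 * h * comp / (h + comp)
    return float(h), float(comp), float(v)


def match_clusters(true_labels, pred_labels) -> list[tuple[int | None, int | None]]:
    """Optimal one-to-one matching of true to predicted clusters.

    Maximizes total overlap on the contingency table (Hungarian
    assignment); clusters without a partner pair with ``None``.  Indices
    refer to the factorized label order (order of first appearance).
    """
    C = _contingency(true_labels, pred_labels)
    T, P = C.shape
    size = max(T, P)
    padded = np.zeros((size, size), dtype=np.int64)
    padded[:T, :P] = C
    rows, cols = linear_sum_assignment(-padded)
    pairs = []
    for r, c in zip(rows, cols):
        pairs.append((r if r < T else None, c if c < P else None))
    return pairs


def prevalence_mae(true_labels, pred_labels) -> float:
    """Mean absolute error between matched cluster frequency vectors.

    Unmatched clusters on either side contribute a frequency-0 phantom.
    """
    true_labels, pred_labels = np.asarray(true_labels), np.asarray(pred_labels)
    n = len(true_labels)
    C = _contingency(true_labels, pred_labels)
    tf = C.sum(axis=1) / n
    pf = C.sum(axis=0) / n
    pairs = match_clusters(true_labels, pred_labels)
    errs = []
    for t, p in pairs:
        ft = tf[t] if t is not None else 0.0
        fp = pf[p] if p is not None else 0.0
        errs.append(abs(ft - fp))
    return float(np.mean(errs))


def epigenotype_hamming(true_states, inferred_states, mask=None) -> float:
    """Proportion of discordant entries between two binary state arrays.

    ``mask`` optionally restricts the comparison (e.g. to entries that
    were missing in the observed matrix).  Returns NaN when no entries
    are comparable.
    """
    a = np.asarray(true_states)
    b = np.asarray(inferred_states)
    if a.shape != b.shape:
        raise ValueError("state arrays must have equal shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        return float("nan")
    return float((a[m] != b[m]).mean())


def cluster_hamming(true_labels, true_profiles, pred_labels, inferred_profiles) -> float:
    """Hamming distance between matched cluster epigenotypes.

    Clusters are matched by maximum overlap; only matched pairs compare.
    Profiles are indexed by factorized label codes.
    """
    pairs = match_clusters(true_labels, pred_labels)
    true_codes = pd.factorize(np.asarray(true_labels))[1]
    pred_codes = pd.factorize(np.asarray(pred_labels))[1]
    dists = []
    for t, p in pairs:
        if t is None or p is None:
            continue
        dists.append(
            epigenotype_hamming(
                true_profiles[int(true_codes[t])], inferred_profiles[int(pred_codes[p])]
            )
        )
    return float(np.mean(dists)) if dists else float("nan")


def uncertainty_tpr(
    dataset, resp: np.ndarray, flag_threshold: float = 0.95
) -> float:
    """Recall of genuinely ambiguous cells among uncertainty-flagged cells.

    A cell is truly ambiguous iff, restricted to its observed loci, its
    true cluster's epigenotype coincides with some other cluster's; it is
    flagged iff its maximum assignment probability is below
    ``flag_threshold``.  Returns NaN when no cell is ambiguous.
    """
    profiles = dataset.cluster_epigenotypes
    obs = dataset.observed.observed
    labels = dataset.true_labels
    K = profiles.shape[0]
    n_amb = 0
    n_hit = 0
    flagged = resp.max(axis=1) < flag_threshold
    for n in range(len(labels)):
        o = obs[n]
        own = profiles[labels[n], o]
        ambiguous = any(
            k != labels[n] and np.array_equal(own, profiles[k, o]) for k in range(K)
        )
        if ambiguous:
            n_amb += 1
            if flagged[n]:
                n_hit += 1
    if n_amb == 0:
        return float("nan")
    return n_hit / n_amb


def coclustering(true_labels, pred_labels) -> pd.DataFrame:
    """True x predicted table of row percentages.

    Entry (i, j) is the percentage of cells of true class i found in
    predicted cluster j; each row sums to 100.
    """
    true_labels, pred_labels = np.asarray(true_labels), np.asarray(pred_labels)
    t_codes, t_uniq = pd.factorize(true_labels)
    p_codes, p_uniq = pd.factorize(pred_labels)
    C = np.zeros((len(t_uniq), len(p_uniq)), dtype=float)
    np.add.at(C, (t_codes, p_codes), 1.0)
    rows = C.sum(axis=1, keepdims=True)
    table = 100.0 * C / rows
    return pd.DataFrame(table, index=list(t_uniq), columns=list(p_uniq))


@dataclass
class MetricsReport:
    """All performance measures for one clustering result."""

    homogeneity: float
    completeness: float
    v_measure: float
    predicted_k: int
    prevalence_mae: float
    hamming: dict[str, float] = field(default_factory=dict)
    uncertainty_tpr: float = float("nan")
    coclustering: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "v_measure": self.v_measure,
            "predicted_k": self.predicted_k,
            "prevalence_mae": self.prevalence_mae,
            "uncertainty_tpr": self.uncertainty_tpr,
        }
        for name, val in self.hamming.items():
            out[f"hamming_{name}"] = val
        return out


def evaluate_result(dataset, results, flag_threshold: float = 0.95) -> MetricsReport:
    """Score a mixture fit against a synthetic dataset's ground truth.

    Hamming distances compare the cell-level imputed states with the true
    cell epigenotypes on the originally-missing entries, for the three
    imputation variants.
    """
    truth = dataset.true_labels
    pred = results.map_labels
    h, c, v = v_measure(truth, pred)
    mae = prevalence_mae(truth, pred)
    missing_mask = ~dataset.observed.observed
    hams = {}
    for variant in ("unadjusted", "adjusted", "naive"):
        imputed = results.impute(variant)
        hams[variant] = epigenotype_hamming(
            dataset.cell_epigenotypes, imputed, mask=missing_mask
        )
    tpr = uncertainty_tpr(dataset, results.resp, flag_threshold)
    return MetricsReport(
        homogeneity=h,
        completeness=c,
        v_measure=v,
        predicted_k=results.n_clusters_found,
        prevalence_mae=mae,
        hamming=hams,
        uncertainty_tpr=tpr,
        coclustering=coclustering(truth, pred),
    )
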