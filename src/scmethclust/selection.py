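"""Multi-restart fitting and DIC-based choice of the number of clusters.

The variational optimization is non-convex, so the mixture model is
fitted many times: first from "informed" partitions — the hierarchical
baselines cut at 1..Kmax clusters plus one density-method partition —
then from random one-hot assignments whose initial cluster count is
uniform on {1..Kmax}.  Each run reports its occupied cluster count c and
DIC.  The number of clusters is chosen from the curve of minimum DIC per
c: keep the longest prefix along which the DIC keeps decreasing by at
least a small relative threshold (0.2% by default), rescale both axes of
the retained prefix to [0, 1], and take the point farthest from the
chord joining its endpoints (the elbow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import (
    density_method,
    euclidean_clust,
    hamming_clust,
    pearson_clust,
)
from .io import region_means
from .matrix import CellMethylationMatrix
from .model import BernoulliMixtureModel, BernoulliMixtureResults, Hyperparams

logger = logging.getLogger(__name__)

__all__ = [
    "informed_initializations",
    "run_restarts",
    "select_best",
    "RunTable",
    "ClusterSelection",
]


def informed_initializations(
    matrix: CellMethylationMatrix,
    kmax: int = 10,
    means: pd.DataFrame | None = None,
    density_plugin=None,
) -> list[tuple[str, np.ndarray]]:
    """Partitions from the non-probabilistic methods, as (source, labels).

    Each hierarchical method that succeeds contributes its tree cut at
    1..kmax clusters; the density method contributes one partition.
    Failures are logged and skipped — with all four sources succeeding at
    kmax = 10 this yields 31 partitions.
    """
    if means is None:
        means = region_means(matrix)
    out: list[tuple[str, np.ndarray]] = []

    def tree_partitions(name, fn, *args):
        try:
            res = fn(*args, kmax=kmax)
        except Exception as exc:  # sparse failures are expected, not fatal
            logger.warning("informed init: %s failed (%s)", name, exc)
            return
        for k in sorted(res.partitions):
            out.append((f"{name}_k{k}", res.partitions[k]))

    tree_partitions("euclidean", euclidean_clust, means)
    tree_partitions("hamming", hamming_clust, matrix)
    tree_partitions("pearson", pearson_clust, matrix)
    try:
        labels = density_method(means, plugin=density_plugin)
        if len(np.unique(labels)) > kmax:
            logger.warning(
                "informed init: density partition has more than %d clusters; "
                "skipped", kmax,
            )
        else:
            out.append(("density", labels))
    except Exception as exc:
        logger.warning("informed init: density method failed (%s)", exc)
    return out


@dataclass
class RunTable:
    """Record of every restart: init source, c, DIC, ELBO, seed."""

    df: pd.DataFrame
    fits: list[BernoulliMixtureResults] = field(default_factory=list, repr=False)

    @property
    def n_runs(self) -> int:
        return len(self.df)

    @property
    def n_informed(self) -> int:
        return int((self.df["init_source"] != "random").sum())


def run_restarts(
    matrix,
    n_restarts: int = 300,
    kmax: int = 10,
    hyperparams: Hyperparams | None = None,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iters: int = 1000,
    shared_region: bool = False,
    informed: list[tuple[str, np.ndarray]] | None = None,
    density_plugin=None,
) -> RunTable:
    """Fit the mixture from informed then random initializations.

    Informed partitions (computed if not supplied) occupy the first
    min(I, T) runs; the remaining runs are random.  Per-run seeds derive
    deterministically from the master ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if informed is None and isinstance(matrix, CellMethylationMatrix):
        informed = informed_initializations(
            matrix, kmax=kmax, density_plugin=density_plugin
        )
    informed = informed or []

    model = BernoulliMixtureModel(
        matrix, kmax, hyperparams=hyperparams, shared_region=shared_region
    )
    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_restarts)

    rows, fits = [], []
    n_failed = 0
    for run_id in range(n_restarts):
        if run_id < len(informed):
            source, init = informed[run_id]
        else:
            source, init = "random", "random"
        rng = np.random.default_rng(child_seeds[run_id])
        try:
            res = model.fit(init=init, tol=tol, max_iters=max_iters, rng=rng)
        except Exception as exc:
            logger.warning("run %d (%s) failed: %s", run_id, source, exc)
            n_failed += 1
            continue
        rows.append(
            {
                "run_id": run_id,
                "init_source": source,
                "c": res.n_clusters_found,
                "dic": res.dic,
                "elbo": res.elbo,
                "seed": int(child_seeds[run_id].generate_state(1)[0] % 2**31),
            }
        )
        fits.append(res)
    if not rows:
        raise RuntimeError(f"all {n_restarts} restarts failed numerically")
    if n_failed:
        logger.warning("%d of %d restarts failed", n_failed, n_restarts)
    return RunTable(pd.DataFrame(rows), fits)


@dataclass
class ClusterSelection:
    """Outcome of the DIC-elbow selection over a run table."""

    n_clusters: int
    best_run_id: int
    best_fit: BernoulliMixtureResults | None
    dic_curve: pd.DataFrame          # columns c, dic; all distinct c
    retained: pd.DataFrame           # the decreasing prefix; elbow lies here

    def summary(self) -> str:
        lines = [
            "Cluster-number selection (DIC elbow)",
            "=" * 38,
            f"selected clusters     {self.n_clusters}",
            f"best run              {self.best_run_id}",
            "DIC curve:",
        ]
        for row in self.dic_curve.itertuples(index=False):
            mark = " *" if row.c == self.n_clusters else ""
            lines.append(f"  c={row.c:<3d} min DIC {row.dic:.2f}{mark}")
        return "\n".join(lines)


def _elbow(points: np.ndarray, n_candidates: int) -> int:
    """Index of the candidate point farthest from the chord.

    Both axes are rescaled to [0, 1] before measuring perpendicular
    distance to the chord joining the first and last point; only the
    first ``n_candidates`` points are eligible (the chord may end on a
    boundary anchor that is not itself selectable).
    """
    x, y = points[:, 0].astype(float), points[:, 1].astype(float)
    xs = (x - x.min()) / (x.max() - x.min()) if x.max() > x.min() else x * 0
    ys = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else y * 0
    x0, y0, x1, y1 = xs[0], ys[0], xs[-1], ys[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        return 0
    dist = np.abs((y1 - y0) * xs - (x1 - x0) * ys + x1 * y0 - y1 * x0) / norm
    return int(np.argmax(dist[:n_candidates]))


def select_best(
    table: RunTable,
    decrease_threshold: float = 0.002,
) -> ClusterSelection:
    """Choose the cluster count and best run from a restart table.

    Build the curve of minimum DIC per recommended c (ascending c); keep
    the longest prefix along which each step decreases the DIC by at
    least ``decrease_threshold`` relative.  The elbow is the retained
    point farthest (on [0, 1]-rescaled axes) from the chord; when the
    prefix ends because the curve stopped decreasing, the first
    non-qualifying point anchors the far end of the chord so the
    flattening corner is geometrically visible — without it, a curve
    that flattens exactly at the true cluster count would put the corner
    at the chord's endpoint, at distance zero, and the rule would
    systematically return one cluster too few.  The best run is the
    minimum-DIC run among those recommending the elbow c (ties: highest
    ELBO, then lowest run id).
    """
    df = table.df
    if df.empty:
        raise ValueError("empty run table")
    curve = (
        df.groupby("c")["dic"].min().reset_index().sort_values("c").reset_index(drop=True)
    )
    # decreasing prefix
    keep = 1
    while keep < len(curve):
        prev_dic = curve.loc[keep - 1, "dic"]
        if curve.loc[keep, "dic"] <= prev_dic * (1.0 - decrease_threshold):
            keep += 1
        else:
            break
    retained = curve.iloc[:keep].reset_index(drop=True)
    # chord anchor: the point at which the decrease rule first failed
    with_anchor = curve.iloc[: min(keep + 1, len(curve))].reset_index(drop=True)

    if len(with_anchor) == 1:
        c_star = int(retained.loc[0, "c"])
    elif len(retained) == 1:
        # flat from the start: no qualifying decrease anywhere
        c_star = int(retained.loc[0, "c"])
    elif len(retained) == 2 and len(with_anchor) == 2:
        # chord distance is degenerate; take the lower-DIC point
        c_star = int(retained.loc[1, "c"])
    else:
        idx = _elbow(with_anchor[["c", "dic"]].to_numpy(), n_candidates=keep)
        c_star = int(retained.loc[idx, "c"])

    cands = df[df["c"] == c_star].sort_values(
        ["dic", "elbo", "run_id"], ascending=[True, False, True]
    )
    best_row = cands.iloc[0]
    best_fit = None
    if table.fits:
        pos = df.index[df["run_id"] == best_row["run_id"]][0]
        best_fit = table.fits[pos]
    return ClusterSelection(
        n_clusters=c_star,
        best_run_id=int(best_row["run_id"]),
        best_fit=best_fit,
        dic_curve=curve,
        retained=retained,
    )


def plot_dic_curve(selection: ClusterSelection, ax=None):
    """DIC-vs-c curve with the retained prefix and chosen elbow marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    ax.plot(selection.dic_curve["c"], selection.dic_curve["dic"], "o-", label="min DIC")
    ax.plot(
        selection.retained["c"],
        selection.retained["dic"],
        "o-",
        color="tab:green",
        label="retained prefix",
    )
    ax.axvline(selection.n_clusters, color="tab:red", ls="--", label="selected c")
    ax.set_xlabel("number of clusters c")
    ax.set_ylabel("DIC")
    ax.legend()
    return ax
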