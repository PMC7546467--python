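"""Hierarchical Bernoulli mixture model for sparse binary methylation
matrices, fitted by mean-field variational Bayes.

Model
-----
Cell ``n`` belongs to a latent epiclone ``Z_n`` in {1..K} with mixture
weights ``pi ~ Dirichlet(alpha0)``.  Epiclone ``k`` carries a hidden binary
epigenotype ``G_krl`` per locus ``l`` of genomic region ``r``; within a
region the states are i.i.d. categorical with region-level methylation
propensity ``mu_kr ~ Dirichlet(beta0)``.  An observed entry is the hidden
state passed through a misclassification (sequencing error) channel::

    P(X_nrl = t | Z_n = k, G_krl = s) = eps_st,   eps_s ~ Dirichlet(gamma0_s)

Missing entries simply contribute no likelihood term.  The "region-free"
variant of the model — all loci share one methylation propensity — is the
special case R = 1 (``shared_region=True``).

Inference maximizes the evidence lower bound (ELBO) over the factored
posterior ``q(Z) q(G) q(pi) q(mu) q(eps)``.  Coordinate updates run in the
fixed order q(G) -> q(Z) -> Dirichlet posteriors, which keeps the ELBO
non-decreasing.  All computation is in the log domain with max-subtraction
before exponentiation.

The model selection score is a conditional deviance information criterion:
``DIC = 2 * Dbar - Dhat`` where ``Dbar = -2 E_q[log p(X | Z, G, eps)]`` and
``Dhat`` is the deviance at the MAP labels, MAP epigenotypes and
posterior-mean error rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, xlogy

from .matrix import MISSING, CellMethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "FixedParams",
    "VariationalState",
    "BernoulliMixtureModel",
    "BernoulliMixtureResults",
    "fit_mixture",
]


@dataclass(frozen=True)
class Hyperparams:
    """Dirichlet prior hyperparameters.

    ``alpha0`` — mixture-weight prior (scalar = symmetric); ``beta0`` —
    prior over the two methylation states of every region propensity;
    ``gamma0`` — per-true-state prior over observed states, biased to the
    diagonal by default so the error channel starts near the identity.
    """

    alpha0: float = 1.0
    beta0: tuple[float, float] = (1.0, 1.0)
    gamma0: tuple[tuple[float, float], tuple[float, float]] = ((99.0, 1.0), (1.0, 99.0))

    def __post_init__(self):
        g = np.asarray(self.gamma0, dtype=float)
        if np.any(np.asarray(self.beta0) <= 0) or np.any(g <= 0) or np.any(
            np.asarray(self.alpha0) <= 0
        ):
            raise ValueError("all hyperparameters must be > 0")


@dataclass(frozen=True)
class FixedParams:
    """Known model parameters (pi, mu, eps) for fixed-parameter inference.

    With fixed parameters only q(Z) and q(G) are updated; used for
    validating the variational posterior against exact enumeration.
    """

    pi: np.ndarray          # K
    mu: np.ndarray          # K x R x 2
    eps: np.ndarray         # 2 x 2, rows = true state s, cols = observed t


@dataclass
class VariationalState:
    resp: np.ndarray                 # N x K, q(Z_n = k)
    phi: np.ndarray                  # K x M x 2, q(G at column m of cluster k)
    alpha_star: np.ndarray | None    # K
    beta_star: np.ndarray | None     # K x R x 2
    gamma_star: np.ndarray | None    # 2 x 2
    elbo_trace: list[float] = field(default_factory=list)

    def copy(self) -> "VariationalState":
        return VariationalState(
            resp=self.resp.copy(),
            phi=self.phi.copy(),
            alpha_star=None if self.alpha_star is None else self.alpha_star.copy(),
            beta_star=None if self.beta_star is None else self.beta_star.copy(),
            gamma_star=None if self.gamma_star is None else self.gamma_star.copy(),
            elbo_trace=list(self.elbo_trace),
        )


def _dirichlet_elog(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return digamma(a) - digamma(a.sum(axis=axis, keepdims=True))


def _dirichlet_kl(a_post: np.ndarray, a_prior: np.ndarray, axis: int = -1) -> np.ndarray:
    """KL(Dir(a_post) || Dir(a_prior)), reduced over ``axis``."""
    sp = a_post.sum(axis=axis)
    s0 = a_prior.sum(axis=axis)
    elog = _dirichlet_elog(a_post, axis=axis)
    return (
        gammaln(sp)
        - gammaln(a_post).sum(axis=axis)
        - gammaln(s0)
        + gammaln(a_prior).sum(axis=axis)
        + ((a_post - a_prior) * elog).sum(axis=axis)
    )


class NumericalError(RuntimeError):
    """A non-finite intermediate in a variational update."""


class BernoulliMixtureModel:
    """Mixture model over a ternary cell x CpG matrix.

    Parameters
    ----------
    data : CellMethylationMatrix or array
        Ternary matrix; arrays use -1 (or NaN) for missing entries.
    n_clusters : int
        Number of mixture components K (an upper bound; empty components
        are pruned in the reported cluster count).
    hyperparams : Hyperparams, optional
    shared_region : bool
        Fit the region-free variant: all loci share a single methylation
        propensity (equivalent to one region spanning the matrix).
    region_index : array, optional
        Column -> region mapping when ``data`` is a bare array.
    fixed_params : FixedParams, optional
        Hold (pi, mu, eps) fixed and infer only q(Z), q(G).
    """

    def __init__(
        self,
        data,
        n_clusters: int,
        hyperparams: Hyperparams | None = None,
        shared_region: bool = False,
        region_index=None,
        fixed_params: FixedParams | None = None,
    ) -> None:
        if n_clusters < 1:
            raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
        self.K = int(n_clusters)
        self.hyper = hyperparams or Hyperparams()
        self.fixed_params = fixed_params

        if isinstance(data, CellMethylationMatrix):
            vals = data.values.astype(float)
            vals[data.values == MISSING] = np.nan
            ridx = data.region_index.copy()
            self.matrix = data
        else:
            vals = np.asarray(data, dtype=float).copy()
            vals[vals == MISSING] = np.nan
            ridx = (
                np.zeros(vals.shape[1], dtype=np.int64)
                if region_index is None
                else np.asarray(region_index, dtype=np.int64)
            )
            self.matrix = None
        if shared_region:
            ridx = np.zeros(vals.shape[1], dtype=np.int64)

        self.N, self.M = vals.shape
        obs = np.isfinite(vals)
        self._X1 = (obs & (vals == 1)).astype(float)
        self._X0 = (obs & (vals == 0)).astype(float)
        self._n_obs = int(obs.sum())
        self.all_missing_cells = np.where(~obs.any(axis=1))[0]

        # columns must be grouped by region for segment sums; reorder if not
        order = np.argsort(ridx, kind="stable")
        self._col_order = order if not np.array_equal(order, np.arange(self.M)) else None
        if self._col_order is not None:
            ridx = ridx[order]
            self._X1 = self._X1[:, order]
            self._X0 = self._X0[:, order]
        # consecutive region codes (input codes may have gaps)
        _uniq, ridx = np.unique(ridx, return_inverse=True)
        self.region_index = ridx
        self.R = len(_uniq) if self.M else 0
        starts = np.flatnonzero(np.r_[True, np.diff(ridx) != 0])
        self._region_starts = starts

        h = self.hyper
        self._alpha0 = np.broadcast_to(np.asarray(h.alpha0, float), (self.K,)).copy()
        self._beta0 = np.broadcast_to(
            np.asarray(h.beta0, float), (self.K, self.R, 2)
        ).copy()
        self._gamma0 = np.asarray(h.gamma0, dtype=float).copy()

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------
    def init_state(self, init="random", rng=None) -> VariationalState:
        """Initial variational state.

        ``init`` is either the string ``"random"`` — an initial cluster
        count is drawn uniformly from {1..K} and cells are assigned to it
        uniformly — or a per-cell label vector; responsibilities start
        one-hot at the assignment and the Dirichlet posteriors start at
        their prior hyperparameters.
        """
        rng = np.random.default_rng(rng)
        if isinstance(init, str):
            if init != "random":
                raise ValueError(f"unknown init {init!r}")
            c0 = int(rng.integers(1, self.K + 1))
            labels = rng.integers(0, c0, size=self.N)
        else:
            labels = np.asarray(init)
            labels = self._codes(labels)
        resp = np.zeros((self.N, self.K))
        resp[np.arange(self.N), labels] = 1.0
        phi = np.full((self.K, self.M, 2), 0.5)
        state = VariationalState(
            resp=resp,
            phi=phi,
            alpha_star=None if self.fixed_params else self._alpha0.copy(),
            beta_star=None if self.fixed_params else self._beta0.copy(),
            gamma_star=None if self.fixed_params else self._gamma0.copy(),
        )
        return state

    def _codes(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        if labels.shape != (self.N,):
            raise ValueError("partition init must give one label per cell")
        if np.issubdtype(labels.dtype, np.integer):
            # 1-based partitions take precedence (labels in {1..K});
            # 0-based partitions are recognised by containing a 0
            if labels.min() >= 1 and labels.max() <= self.K:
                return labels.astype(np.int64) - 1
            if labels.min() >= 0 and labels.max() < self.K:
                return labels.astype(np.int64)
        uniq, codes = np.unique(labels, return_inverse=True)
        if len(uniq) > self.K:
            raise ValueError(
                f"partition has {len(uniq)} clusters but K = {self.K}"
            )
        return codes

    # ------------------------------------------------------------------
    # expectations
    # ------------------------------------------------------------------
    def _expectations(self, state: VariationalState):
        if self.fixed_params is not None:
            fp = self.fixed_params
            elog_pi = np.log(fp.pi)
            elog_mu = np.log(fp.mu)
            elog_eps = np.log(fp.eps)
        else:
            elog_pi = _dirichlet_elog(state.alpha_star)
            elog_mu = _dirichlet_elog(state.beta_star)          # K x R x 2
            elog_eps = _dirichlet_elog(state.gamma_star)        # 2 x 2
        return elog_pi, elog_mu, elog_eps

    # ------------------------------------------------------------------
    # one full coordinate sweep
    # ------------------------------------------------------------------
    def sweep(self, state: VariationalState) -> VariationalState:
        """One full update in fixed order q(G) -> q(Z) -> Dirichlets."""
        elog_pi, elog_mu, elog_eps = self._expectations(state)
        ridx = self.region_index

        # --- q(G) ---
        C0 = state.resp.T @ self._X0          # K x M observed-0 weight
        C1 = state.resp.T @ self._X1
        log_phi = np.empty((self.K, self.M, 2))
        for s in (0, 1):
            log_phi[:, :, s] = (
                elog_mu[:, ridx, s] + C0 * elog_eps[s, 0] + C1 * elog_eps[s, 1]
            )
        log_phi -= log_phi.max(axis=2, keepdims=True)
        phi = np.exp(log_phi)
        phi /= phi.sum(axis=2, keepdims=True)
        if not np.isfinite(phi).all():
            raise NumericalError("non-finite value in the q(G) update")
        state.phi = phi

        # --- q(Z) ---
        W0 = phi[:, :, 0] * elog_eps[0, 0] + phi[:, :, 1] * elog_eps[1, 0]
        W1 = phi[:, :, 0] * elog_eps[0, 1] + phi[:, :, 1] * elog_eps[1, 1]
        log_resp = elog_pi[None, :] + self._X0 @ W0.T + self._X1 @ W1.T
        log_resp -= logsumexp(log_resp, axis=1, keepdims=True)
        resp = np.exp(log_resp)
        if not np.isfinite(resp).all():
            raise NumericalError("non-finite value in the q(Z) update")
        state.resp = resp

        # --- Dirichlet posteriors ---
        if self.fixed_params is None:
            state.alpha_star = self._alpha0 + resp.sum(axis=0)
            seg = np.add.reduceat(phi, self._region_starts, axis=1)  # K x R x 2
            state.beta_star = self._beta0 + seg
            C0 = resp.T @ self._X0
            C1 = resp.T @ self._X1
            gamma = self._gamma0.copy()
            for s in (0, 1):
                gamma[s, 0] += (phi[:, :, s] * C0).sum()
                gamma[s, 1] += (phi[:, :, s] * C1).sum()
            if not np.isfinite(gamma).all():
                raise NumericalError("non-finite value in the Dirichlet update")
            state.gamma_star = gamma
        return state

    # ------------------------------------------------------------------
    # ELBO
    # ------------------------------------------------------------------
    def elbo(self, state: VariationalState) -> float:
        elog_pi, elog_mu, elog_eps = self._expectations(state)
        resp, phi = state.resp, state.phi
        ridx = self.region_index

        C0 = resp.T @ self._X0
        C1 = resp.T @ self._X1
        ll = 0.0
        for s in (0, 1):
            ll += (phi[:, :, s] * (C0 * elog_eps[s, 0] + C1 * elog_eps[s, 1])).sum()

        ez = (resp * elog_pi[None, :]).sum()
        eg = sum((phi[:, :, s] * elog_mu[:, ridx, s]).sum() for s in (0, 1))
        ent_z = -xlogy(resp, resp).sum()
        ent_g = -xlogy(phi, phi).sum()

        total = ll + ez + eg + ent_z + ent_g
        if self.fixed_params is None:
            total -= _dirichlet_kl(state.alpha_star, self._alpha0)
            total -= _dirichlet_kl(state.beta_star, self._beta0).sum()
            total -= _dirichlet_kl(state.gamma_star, self._gamma0).sum()
        if not np.isfinite(total):
            raise NumericalError("non-finite ELBO")
        return float(total)

    def _expected_loglik(self, state: VariationalState) -> float:
        """E_q[log p(X | Z, G, eps)] — the data term of the ELBO."""
        _ep, _em, elog_eps = self._expectations(state)
        C0 = state.resp.T @ self._X0
        C1 = state.resp.T @ self._X1
        out = 0.0
        for s in (0, 1):
            out += (
                state.phi[:, :, s] * (C0 * elog_eps[s, 0] + C1 * elog_eps[s, 1])
            ).sum()
        return float(out)

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(
        self,
        init="random",
        tol: float = 1e-6,
        max_iters: int = 1000,
        rng=None,
    ) -> "BernoulliMixtureResults":
        """Run coordinate ascent to convergence of the ELBO.

        Convergence: relative ELBO change below ``tol``.  Non-convergence
        within ``max_iters`` is flagged on the results, not fatal.
        """
        rng = np.random.default_rng(rng)
        state = self.init_state(init, rng=rng)
        converged = False
        n_iters = 0
        prev = -np.inf
        for n_iters in range(1, max_iters + 1):
            self.sweep(state)
            cur = self.elbo(state)
            state.elbo_trace.append(cur)
            if np.isfinite(prev):
                denom = max(abs(prev), 1e-12)
                if abs(cur - prev) / denom < tol:
                    converged = True
                    break
            prev = cur
        if not converged:
            logger.debug("VB did not converge in %d iterations", max_iters)
        return BernoulliMixtureResults(self, state, converged, n_iters)


class BernoulliMixtureResults:
    """Results of one variational fit.

    Attributes
    ----------
    map_labels : int array (N,)
        Per-cell argmax cluster assignment, relabeled to consecutive
        ``0..c-1`` in order of first appearance of the raw labels.
    n_clusters_found : int
        Number of occupied clusters c under the MAP assignment.
    dic : float
        Deviance information criterion of the fit (lazy).
    map_epigenotypes : int8 array (K, M)
        Per-cluster argmax hidden methylation states (raw cluster order).
    """

    def __init__(self, model, state, converged, n_iters):
        self.model = model
        self.state = state
        self.converged = bool(converged)
        self.n_iters = int(n_iters)
        raw = np.argmax(state.resp, axis=1)
        self._raw_labels = raw
        uniq = list(dict.fromkeys(raw.tolist()))
        remap = {k: i for i, k in enumerate(uniq)}
        self.map_labels = np.array([remap[k] for k in raw], dtype=np.int64)
        self.n_clusters_found = len(uniq)
        self._occupied = np.array(uniq, dtype=np.int64)
        self._dic = None

    # aliases matching the field's usual result-attribute spellings
    @property
    def c(self) -> int:
        return self.n_clusters_found

    @property
    def elbo(self) -> float:
        return self.state.elbo_trace[-1] if self.state.elbo_trace else np.nan

    @property
    def resp(self) -> np.ndarray:
        return self.state.resp

    @property
    def map_epigenotypes(self) -> np.ndarray:
        phi = self.state.phi
        return (phi[:, :, 1] > phi[:, :, 0]).astype(np.int8)

    @property
    def pi_mean(self) -> np.ndarray:
        a = self.state.alpha_star
        return a / a.sum() if a is not None else self.model.fixed_params.pi

    @property
    def mu_mean(self) -> np.ndarray:
        b = self.state.beta_star
        if b is None:
            return self.model.fixed_params.mu
        return b / b.sum(axis=-1, keepdims=True)

    @property
    def epsilon_mean(self) -> np.ndarray:
        g = self.state.gamma_star
        if g is None:
            return self.model.fixed_params.eps
        return g / g.sum(axis=-1, keepdims=True)

    # ------------------------------------------------------------------
    @property
    def dic(self) -> float:
        if self._dic is None:
            self._dic = self._compute_dic()
        return self._dic

    def _compute_dic(self) -> float:
        m = self.model
        dbar = -2.0 * m._expected_loglik(self.state)
        # plug-in deviance at MAP labels, MAP epigenotypes, mean error rates
        eps_bar = self.epsilon_mean
        log_eps = np.log(np.clip(eps_bar, 1e-300, None))
        g_cell = self.map_epigenotypes[self._raw_labels]  # N x M
        l0 = np.where(g_cell == 1, log_eps[1, 0], log_eps[0, 0])
        l1 = np.where(g_cell == 1, log_eps[1, 1], log_eps[0, 1])
        dhat = -2.0 * float((m._X0 * l0).sum() + (m._X1 * l1).sum())
        return 2.0 * dbar - dhat

    # ------------------------------------------------------------------
    def impute(self, variant: str = "unadjusted") -> np.ndarray:
        """Complete N x M binary matrix; observed entries pass through.

        ``unadjusted`` — MAP epigenotype of the cell's MAP cluster;
        ``adjusted`` — argmax of the responsibility-weighted mixture of
        cluster state posteriors; ``naive`` — majority vote of observed
        values among MAP cluster-mates (falling back to the overall
        column majority, then to 0).
        """
        m = self.model
        obs1 = m._X1.astype(bool)
        obs0 = m._X0.astype(bool)
        observed = obs1 | obs0
        out = np.zeros((m.N, m.M), dtype=np.int8)
        out[obs1] = 1

        if variant == "unadjusted":
            fill = self.map_epigenotypes[self._raw_labels]
        elif variant == "adjusted":
            mix = np.einsum("nk,kms->nms", self.state.resp, self.state.phi)
            fill = (mix[:, :, 1] > mix[:, :, 0]).astype(np.int8)
        elif variant == "naive":
            fill = self._naive_fill(obs0, obs1)
        else:
            raise ValueError(f"unknown imputation variant {variant!r}")
        if m._col_order is not None:
            # model columns were reordered by region; map back
            inv = np.empty(m.M, dtype=np.int64)
            inv[m._col_order] = np.arange(m.M)
            out_full = np.where(observed, out, fill)
            return out_full[:, inv]
        return np.where(observed, out, fill)

    def _naive_fill(self, obs0, obs1) -> np.ndarray:
        labels = self._raw_labels
        n1 = obs1.astype(float)
        n0 = obs0.astype(float)
        g1 = np.zeros((self.model.K, self.model.M))
        g0 = np.zeros((self.model.K, self.model.M))
        np.add.at(g1, labels, n1)
        np.add.at(g0, labels, n0)
        tot1, tot0 = n1.sum(axis=0), n0.sum(axis=0)
        col_major = np.where(
            tot1 > tot0, 1, np.where(tot1 < tot0, 0, np.where(tot1 > 0, -2, -2))
        )
        # column fallback: strict majority over all cells, ties/no data -> 0
        col_fill = np.where(col_major == -2, 0, col_major).astype(np.int8)
        grp1, grp0 = g1[labels], g0[labels]
        fill = np.where(
            grp1 > grp0, 1, np.where(grp1 < grp0, 0, -2)
        )
        return np.where(fill == -2, col_fill[None, :], fill).astype(np.int8)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Bernoulli mixture model (variational Bayes)",
            "=" * 46,
            f"cells                 {self.model.N}",
            f"CpG columns           {self.model.M}",
            f"regions               {self.model.R}",
            f"components (K)        {self.model.K}",
            f"occupied clusters (c) {self.n_clusters_found}",
            f"ELBO                  {self.elbo:.4f}",
            f"DIC                   {self.dic:.4f}",
            f"iterations            {self.n_iters}"
            + ("" if self.converged else "  (not converged)"),
        ]
        freqs = np.bincount(self.map_labels, minlength=self.n_clusters_found)
        freqs = freqs / max(len(self.map_labels), 1)
        lines.append(
            "cluster frequencies   "
            + ", ".join(f"{f:.3f}" for f in freqs[: self.n_clusters_found])
        )
        eps = self.epsilon_mean
        lines.append(f"error rate (mean)     {eps[0, 1]:.4f} / {eps[1, 0]:.4f}")
        if len(self.model.all_missing_cells):
            lines.append(
                f"all-missing cells     {len(self.model.all_missing_cells)} (flagged)"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<BernoulliMixtureResults c={self.n_clusters_found} "
            f"elbo={self.elbo:.2f} dic={self.dic:.2f}>"
        )


def fit_mixture(
    matrix,
    n_clusters: int,
    init="random",
    hyperparams: Hyperparams | None = None,
    shared_region: bool = False,
    tol: float = 1e-6,
    max_iters: int = 1000,
    rng=None,
) -> BernoulliMixtureResults:
    """Convenience wrapper: build the model and fit in one call."""
    model = BernoulliMixtureModel(
        matrix, n_clusters, hyperparams=hyperparams, shared_region=shared_region
    )
    return model.fit(init=init, tol=tol, max_iters=max_iters, rng=rng)
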