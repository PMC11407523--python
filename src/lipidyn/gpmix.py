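"""Hierarchical Gaussian-process mixture clustering of trajectories.

Each cluster j has a latent mean function f_j with a GP prior under a
Matern-5/2 kernel (variance 1, lengthscale 2 on the integer stage-code axis
by default); a member curve deviates from its cluster mean by a second GP
(Matern-5/2, variance 0.7, lengthscale 2) plus white noise (variance 0.1).
Kernel hyperparameters are fixed, not optimized.

Fitting is an EM-style alternation over a finite mixture with an
over-specified number of components and mass-based pruning:

* E-step: the responsibility of curve ``y_n`` for cluster j is proportional to
  ``pi_j * N(y_n; mu_j, K_y + Sigma_j)`` where ``(mu_j, Sigma_j)`` is the
  current posterior of the cluster mean at the observed time codes.
* M-step: mixing weights from responsibility mass, and each cluster-mean
  posterior from the responsibility-weighted curve stack: with total mass
  ``R_j`` and weighted mean curve ``ybar_j``,

      A_j     = K_f + K_y / R_j
      mu_j    = K_f A_j^{-1} ybar_j
      Sigma_j = K_f - K_f A_j^{-1} K_f

Clusters whose mixing weight falls below a floor (default ``1/(2N)``) are
pruned.  Initialization is k-means on the curves; several restarts are run
and the best final log-likelihood kept.  Cluster mean curves (with 95% bands)
are predicted at arbitrary query codes by the GP posterior-predictive
formulas under the mean-function kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "Matern52Kernel",
    "WhiteKernel",
    "SumKernel",
    "matern52",
    "build_covariance",
    "default_mean_kernel",
    "default_deviation_kernel",
    "GPTrajectoryMixture",
    "GPMixtureResults",
    "TrajectoryCurve",
    "fit_gp_mixture",
]


def matern52(r, variance: float = 1.0, lengthscale: float = 1.0):
    """Matern-5/2 covariance at distance ``r``:
    sigma^2 (1 + sqrt5 r/l + 5 r^2 / (3 l^2)) exp(-sqrt5 r/l).
    """
    if variance <= 0 or lengthscale <= 0:
        raise ValueError("variance and lengthscale must be > 0")
    r = np.abs(np.asarray(r, dtype=float))
    s = np.sqrt(5.0) * r / lengthscale
    return variance * (1.0 + s + s**2 / 3.0) * np.exp(-s)


@dataclass(frozen=True)
class Matern52Kernel:
    variance: float = 1.0
    lengthscale: float = 1.0

    def __post_init__(self) -> None:
        if self.variance <= 0 or self.lengthscale <= 0:
            raise ValueError("variance and lengthscale must be > 0")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.abs(np.subtract.outer(np.asarray(x, float), np.asarray(y, float)))
        return matern52(r, self.variance, self.lengthscale)


@dataclass(frozen=True)
class WhiteKernel:
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be > 0")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        # contributes only at coincident inputs (the diagonal on a shared grid)
        return self.variance * (np.subtract.outer(x, y) == 0).astype(float)


@dataclass(frozen=True)
class SumKernel:
    components: tuple = ()

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("sum kernel needs >= 2 components")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return sum(k(x, y) for k in self.components)


def default_mean_kernel() -> Matern52Kernel:
    """Cluster-mean-function kernel: Matern-5/2, variance 1, lengthscale 2."""
    return Matern52Kernel(variance=1.0, lengthscale=2.0)


def default_deviation_kernel() -> SumKernel:
    """Member-deviation kernel: Matern-5/2 (0.7, 2) + white noise (0.1)."""
    return SumKernel((Matern52Kernel(0.7, 2.0), WhiteKernel(0.1)))


def build_covariance(time_codes: Sequence[float], kernel) -> np.ndarray:
    """Evaluate a kernel into a symmetric PSD covariance matrix.

    Positive-definiteness is verified by Cholesky after adding at most
    ``1e-8 * trace/n`` of diagonal jitter.
    """
    t = np.asarray(time_codes, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("time codes must be finite")
    K = kernel(t, t)
    K = 0.5 * (K + K.T)
    _chol(K)  # raises if not PD after jitter
    return K


def _chol(K: np.ndarray):
    """Cholesky with escalating jitter up to 1e-8 * mean diagonal."""
    n = K.shape[0]
    base = np.trace(K) / n
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return cho_factor(K + jitter * base * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not positive definite after max jitter")


def _mvn_logpdf(Y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of each row of Y under N(mean, cov)."""
    c, lower = _chol(cov)
    L = np.tril(c)
    diff = (Y - mean).T  # T x N
    sol = solve_triangular(L, diff, lower=True)
    quad = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    T = cov.shape[0]
    return -0.5 * (quad + logdet + T * np.log(2.0 * np.pi))


@dataclass
class TrajectoryCurve:
    """A predicted cluster mean curve with its 95% band."""

    cluster: int
    time_codes: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster,
                "time_code": self.time_codes,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class GPMixtureResults:
    """Fitted GP trajectory mixture.

    ``posterior_means``/``posterior_covs`` hold each surviving cluster's
    latent-mean posterior at the observed time codes; ``responsibilities``
    rows sum to 1 over clusters.
    """

    time_codes: np.ndarray
    weights: np.ndarray  # pi, sums to 1
    posterior_means: np.ndarray  # K x T
    posterior_covs: np.ndarray  # K x T x T
    cluster_mass: np.ndarray  # R_j
    weighted_means: np.ndarray  # ybar_j, K x T
    responsibilities: pd.DataFrame  # feature x cluster
    log_likelihood_trace: np.ndarray
    mean_kernel: object = field(default_factory=default_mean_kernel)
    deviation_kernel: object = field(default_factory=default_deviation_kernel)
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.weights)

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])

    def assign_members(self, threshold: float = 0.8) -> tuple[pd.Series, list[str]]:
        """Hard assignments for features whose top responsibility exceeds
        ``threshold``; the rest are returned as unassigned.
        """
        if not 0 < threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        R = self.responsibilities
        top = R.max(axis=1)
        label = R.to_numpy().argmax(axis=1) + 1
        # strict "> threshold" rule; at threshold = 1 exact certainty qualifies
        mask = top > threshold if threshold < 1.0 else top >= 1.0
        assigned = pd.Series(label, index=R.index, name="cluster")[mask]
        unassigned = list(R.index[~mask])
        return assigned, unassigned

    def predict_cluster_curve(
        self, cluster: int, query_codes: Sequence[float] | None = None
    ) -> TrajectoryCurve:
        """GP posterior-predictive mean and 95% band of a cluster's latent
        mean function at ``query_codes`` (default: integer codes 1..15).
        """
        if not 1 <= cluster <= self.n_clusters:
            raise KeyError(f"unknown cluster {cluster}; model has {self.n_clusters}")
        q = (
            np.arange(1.0, 16.0)
            if query_codes is None
            else np.asarray(query_codes, dtype=float)
        )
        j = cluster - 1
        t = self.time_codes
        K_f = build_covariance(t, self.mean_kernel)
        K_y = build_covariance(t, self.deviation_kernel)
        A = K_f + K_y / self.cluster_mass[j]
        cA = _chol(A)
        alpha = cho_solve(cA, self.weighted_means[j])
        K_qt = self.mean_kernel(q, t)
        mean = K_qt @ alpha
        K_qq = self.mean_kernel(q, q)
        cov = K_qq - K_qt @ cho_solve(cA, K_qt.T)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return TrajectoryCurve(cluster, q, mean, mean - 1.96 * sd, mean + 1.96 * sd)

    def predict_all_curves(
        self, query_codes: Sequence[float] | None = None
    ) -> list[TrajectoryCurve]:
        return [
            self.predict_cluster_curve(j + 1, query_codes)
            for j in range(self.n_clusters)
        ]

    def summary(self) -> str:
        counts = (self.responsibilities.to_numpy().argmax(axis=1) + 1)
        lines = [
            "GP trajectory mixture",
            "=" * 42,
            f"clusters (after pruning)  {self.n_clusters}",
            f"features                  {len(self.responsibilities)}",
            f"log-likelihood            {self.log_likelihood:.4f}",
            f"EM iterations             {len(self.log_likelihood_trace)}",
            f"converged                 {self.converged}",
            "cluster   weight   members(argmax)",
        ]
        for j in range(self.n_clusters):
            lines.append(
                f"  {j+1:<7} {self.weights[j]:<8.3f} {(counts == j + 1).sum()}"
            )
        return "\n".join(lines)


class GPTrajectoryMixture:
    """Finite GP mixture model over feature trajectories.

    Parameters
    ----------
    curves
        Feature x time-code DataFrame (replicates already summarized per
        stage, e.g. by the replicate mean).
    time_codes
        Numeric codes for the columns of ``curves`` (default: parsed from the
        column labels).
    K_init
        Over-specified initial number of clusters; empty clusters are pruned.
    prune_floor
        Minimum mixing weight; default ``1/(2N)``.
    """

    def __init__(
        self,
        curves: pd.DataFrame,
        time_codes: Sequence[float] | None = None,
        K_init: int = 10,
        mean_kernel=None,
        deviation_kernel=None,
        prune_floor: float | None = None,
        tol: float = 1e-6,
        max_iter: int = 200,
        restarts: int = 5,
    ):
        if K_init < 1:
            raise ValueError("K_init must be >= 1")
        if len(curves) < K_init:
            K_init = len(curves)
        self.curves = curves
        self.time_codes = (
            np.asarray(time_codes, float)
            if time_codes is not None
            else np.asarray([float(c) for c in curves.columns])
        )
        if len(self.time_codes) != curves.shape[1]:
            raise ValueError("time_codes length does not match curve columns")
        self.K_init = K_init
        self.mean_kernel = mean_kernel or default_mean_kernel()
        self.deviation_kernel = deviation_kernel or default_deviation_kernel()
        self.prune_floor = prune_floor
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts

    def fit(self, seed: int = 0) -> GPMixtureResults:
        Y = self.curves.to_numpy(dtype=float)
        if not np.isfinite(Y).all():
            raise ValueError("curves must be finite")
        N = Y.shape[0]
        floor = self.prune_floor if self.prune_floor is not None else 1.0 / (2 * N)
        K_f = build_covariance(self.time_codes, self.mean_kernel)
        K_y = build_covariance(self.time_codes, self.deviation_kernel)
        best = None
        for r in range(self.restarts):
            state = self._fit_once(Y, K_f, K_y, floor, seed=seed + r)
            if best is None or state["trace"][-1] > best["trace"][-1]:
                best = state
        if not best["converged"]:
            warnings.warn(
                f"GP mixture EM did not converge in {self.max_iter} iterations; "
                "returning best state"
            )
        K = len(best["pi"])
        resp = pd.DataFrame(
            best["resp"],
            index=self.curves.index,
            columns=[f"cluster_{j+1}" for j in range(K)],
        )
        return GPMixtureResults(
            time_codes=self.time_codes,
            weights=best["pi"],
            posterior_means=best["mu"],
            posterior_covs=best["Sigma"],
            cluster_mass=best["R"],
            weighted_means=best["ybar"],
            responsibilities=resp,
            log_likelihood_trace=np.asarray(best["trace"]),
            mean_kernel=self.mean_kernel,
            deviation_kernel=self.deviation_kernel,
            converged=best["converged"],
        )

    # -- internals ---------------------------------------------------------
    #
    # Coordinate-ascent variational EM.  q(f_j) = N(mu_j, Sigma_j) with the
    # hierarchical-GP update (the posterior of the latent mean given the
    # responsibility-weighted curve stack under prior K_f and noise
    # K_y / R_j); q(z_n) = responsibilities from the variational expected
    # log-likelihood.  The tracked objective is the variational free energy
    # (a lower bound on the log marginal likelihood), which every update —
    # and, in practice, mass pruning, which removes a positive KL penalty —
    # increases, so the trace is monotone up to roundoff.

    def _m_step(self, Y, resp, K_f, K_y):
        N, T = Y.shape
        K = resp.shape[1]
        R = resp.sum(axis=0)  # cluster masses
        pi = R / N
        mu = np.zeros((K, T))
        Sigma = np.zeros((K, T, T))
        ybar = np.zeros((K, T))
        for j in range(K):
            ybar[j] = (resp[:, j] @ Y) / R[j]
            A = K_f + K_y / R[j]
            cA = _chol(A)
            mu[j] = K_f @ cho_solve(cA, ybar[j])
            S = K_f - K_f @ cho_solve(cA, K_f)
            Sigma[j] = 0.5 * (S + S.T)
        return pi, R, ybar, mu, Sigma

    def _e_step(self, Y, pi, mu, Sigma, K_f, K_y):
        """Responsibilities and free energy given the current q(f)."""
        K = len(pi)
        cKy = _chol(K_y)
        cKf = _chol(K_f)
        logdet_Kf = 2.0 * np.log(np.diag(np.tril(cKf[0]))).sum()
        logp = np.zeros((Y.shape[0], K))
        kl = np.zeros(K)
        for j in range(K):
            trace_pen = 0.5 * np.trace(cho_solve(cKy, Sigma[j]))
            logp[:, j] = np.log(pi[j]) + _mvn_logpdf(Y, mu[j], K_y) - trace_pen
            sign, logdet_S = np.linalg.slogdet(Sigma[j])
            kl[j] = 0.5 * (
                np.trace(cho_solve(cKf, Sigma[j]))
                + mu[j] @ cho_solve(cKf, mu[j])
                - Sigma[j].shape[0]
                + logdet_Kf
                - logdet_S
            )
        norm = logsumexp(logp, axis=1)
        resp = np.exp(logp - norm[:, None])
        free_energy = float(norm.sum() - kl.sum())
        return resp, free_energy

    def _vb_iterate(self, Y, resp, K_f, K_y, floor, max_iter, trace):
        """Run VB updates from ``resp`` until convergence; mutates ``trace``."""
        converged = False
        for _ in range(max_iter):
            pi, R, ybar, mu, Sigma = self._m_step(Y, resp, K_f, K_y)
            keep = pi >= floor
            if not keep.all() and keep.sum() >= 1:
                pi, R, ybar, mu, Sigma = (
                    pi[keep] / pi[keep].sum(), R[keep], ybar[keep], mu[keep], Sigma[keep],
                )
            resp, fe = self._e_step(Y, pi, mu, Sigma, K_f, K_y)
            trace.append(fe)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < self.tol * (
                1.0 + abs(trace[-1])
            ):
                converged = True
                break
        return {
            "pi": pi, "R": R, "ybar": ybar, "mu": mu, "Sigma": Sigma,
            "resp": resp, "converged": converged,
        }

    def _merge_phase(self, Y, state, K_f, K_y, floor, trace):
        """Greedy merging of cluster pairs while the free energy improves.

        With fixed kernels, splitting one true cluster into two near-copies
        is a stable local optimum of EM; the free energy's KL penalty makes
        such duplicates strictly worse once merged, so accepted merges undo
        them.  Each candidate merge is refined by a few VB iterations before
        comparison.
        """
        while len(state["pi"]) > 1:
            K = len(state["pi"])
            base_fe = trace[-1]
            best = None
            for i in range(K):
                for j in range(i + 1, K):
                    resp = np.delete(state["resp"], j, axis=1)
                    resp[:, i] = state["resp"][:, i] + state["resp"][:, j]
                    t: list[float] = []
                    cand = self._vb_iterate(Y, resp, K_f, K_y, floor, 15, t)
                    if t[-1] > base_fe + self.tol and (best is None or t[-1] > best[1]):
                        best = (cand, t[-1])
            if best is None:
                break
            state = best[0]
            trace.append(best[1])
        return state

    def _fit_once(self, Y, K_f, K_y, floor, seed):
        N = Y.shape[0]
        K = self.K_init
        if K == 1:
            labels = np.zeros(N, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=3, random_state=seed % (2**31))
            labels = km.fit_predict(Y)
        resp = np.full((N, K), 1e-6)
        resp[np.arange(N), labels] = 1.0
        resp /= resp.sum(axis=1, keepdims=True)

        trace: list[float] = []
        state = self._vb_iterate(Y, resp, K_f, K_y, floor, self.max_iter, trace)
        state = self._merge_phase(Y, state, K_f, K_y, floor, trace)
        state["trace"] = trace
        return state


def fit_gp_mixture(
    curves: pd.DataFrame,
    time_codes: Sequence[float] | None = None,
    K_init: int = 10,
    mean_kernel=None,
    deviation_kernel=None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    restarts: int = 5,
    prune_floor: float | None = None,
) -> GPMixtureResults:
    """Functional front end for :class:`GPTrajectoryMixture` (see class docs)."""
    model = GPTrajectoryMixture(
        curves,
        time_codes=time_codes,
        K_init=K_init,
        mean_kernel=mean_kernel,
        deviation_kernel=deviation_kernel,
        prune_floor=prune_floor,
        tol=tol,
        max_iter=max_iter,
        restarts=restarts,
    )
    return model.fit(seed=seed)
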