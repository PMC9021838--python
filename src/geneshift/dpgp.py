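"""Dirichlet-process Gaussian-process (DP-GP) fine clustering.

Each coarse soft-DTW cluster is refined with a Dirichlet-process mixture of
Gaussian processes: every sub-cluster has a latent smooth mean function
f ~ GP(0, k_SE) on the time grid, and each member trajectory is f plus
i.i.d. Gaussian noise. Inference is collapsed Gibbs sampling over the
Chinese-restaurant-process partition: a trajectory joins an existing
sub-cluster with probability proportional to (cluster size) x the marginal
likelihood ratio, or opens a new one with probability proportional to the
concentration alpha. Post-burn-in partitions accumulate a posterior
co-clustering (similarity) matrix, and the returned partition is the
sampled partition closest (least squares) to that matrix.

The cluster marginal likelihood exploits exchangeability: for n member
series y_1..y_n with shared latent mean,

    log p(y_1..n) = log N(ybar; 0, K + sigma_n^2/n I)
                    - (n-1) T/2 log(2 pi sigma_n^2) - T/2 log n
                    - SS_within / (2 sigma_n^2),

which equals the dense nT-dimensional zero-mean Gaussian with covariance
1 1^T (x) K + sigma_n^2 I but needs only a T x T Cholesky factorization.
GP hyperparameters are estimated once per parent cluster (empirical-Bayes
defaults) and held fixed across sweeps, keeping the sampler fast and
deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "GPHyperparams",
    "FineClustering",
    "se_kernel",
    "estimate_hyperparams",
    "cluster_log_marginal",
    "dpgp_cluster",
]

_JITTER_FRAC = 1e-8
_VAR_FLOOR = 1e-4


@dataclass(frozen=True)
class GPHyperparams:
    """Squared-exponential GP hyperparameters.

    signal_var : marginal variance sigma_f^2 of the latent mean function
    length_scale : correlation length ell in hours
    noise_var : replicate noise variance sigma_n^2
    """

    signal_var: float
    length_scale: float
    noise_var: float

    def __post_init__(self):
        for name in ("signal_var", "length_scale", "noise_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class FineClustering:
    """Partition of one parent cluster into DP-GP sub-clusters."""

    parent_cluster: int
    partition: np.ndarray            # sub-cluster index per member
    similarity: np.ndarray           # posterior co-clustering frequencies
    n_sweeps_run: int
    alpha: float
    seed: int

    def __post_init__(self):
        S = np.asarray(self.similarity, dtype=float)
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("similarity diagonal must be 1")
        labels = np.asarray(self.partition)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("partition labels must be contiguous from 0")

    @property
    def n_subclusters(self) -> int:
        return int(self.partition.max()) + 1

    def mean_series(self, members: np.ndarray) -> dict[int, np.ndarray]:
        """Per-sub-cluster mean trajectory over its members."""
        M = np.asarray(members, dtype=float)
        return {c: M[self.partition == c].mean(axis=0)
                for c in range(self.n_subclusters)}


def se_kernel(t, hp: GPHyperparams) -> np.ndarray:
    """Squared-exponential covariance on a strictly increasing time grid."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time grid must be 1-D and strictly increasing")
    d = t[:, None] - t[None, :]
    return hp.signal_var * np.exp(-(d ** 2) / (2.0 * hp.length_scale ** 2))


def estimate_hyperparams(members, t) -> GPHyperparams:
    """Empirical-Bayes hyperparameter defaults from the member series.

    signal_var = pooled sample variance of all values (floored at 1e-4 with
    a warning for degenerate constant input); noise_var = signal_var / 4
    (same floor); length_scale = half the time-grid span.
    """
    Y = np.asarray(members, dtype=float)
    if Y.size == 0:
        raise ValueError("no member series")
    t = np.asarray(t, dtype=float)
    sf2 = float(np.var(Y, ddof=1)) if Y.size > 1 else 0.0
    if sf2 < _VAR_FLOOR:
        logger.warning("near-zero variance input; flooring signal_var at %g",
                       _VAR_FLOOR)
        sf2 = _VAR_FLOOR
    sn2 = max(0.25 * sf2, _VAR_FLOOR)
    span = float(t[-1] - t[0]) if len(t) > 1 else 1.0
    ell = max(span / 2.0, 1e-6)
    return GPHyperparams(signal_var=sf2, length_scale=ell, noise_var=sn2)


class _MarginalCache:
    """Cholesky factors of K + sigma_n^2/n I, cached per cluster size n."""

    def __init__(self, t, hp: GPHyperparams):
        self.hp = hp
        self.T = len(np.asarray(t))
        K = se_kernel(t, hp)
        self.K = K + _JITTER_FRAC * hp.signal_var * np.eye(self.T)
        self._fact: dict[int, tuple] = {}

    def _factor(self, n: int):
        if n not in self._fact:
            C = self.K + (self.hp.noise_var / n) * np.eye(self.T)
            try:
                cf = cho_factor(C, lower=True)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ValueError(
                    "cluster covariance not positive definite after jitter"
                ) from exc
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            self._fact[n] = (cf, logdet)
        return self._fact[n]

    def logmarg(self, n: int, ysum: np.ndarray, ysumsq: float) -> float:
        """Log marginal of a cluster from its sufficient statistics.

        n: member count; ysum: sum of member series; ysumsq: sum of squares
        of all member values.
        """
        T, sn2 = self.T, self.hp.noise_var
        ybar = ysum / n
        ssw = ysumsq - n * float(ybar @ ybar)
        cf, logdet = self._factor(n)
        quad = float(ybar @ cho_solve(cf, ybar))
        ll_bar = -0.5 * (quad + logdet + T * math.log(2 * math.pi))
        return (ll_bar
                - 0.5 * (n - 1) * T * math.log(2 * math.pi * sn2)
                - 0.5 * T * math.log(n)
                - 0.5 * max(ssw, 0.0) / sn2)


def cluster_log_marginal(members, t, hp: GPHyperparams) -> float:
    """Log marginal likelihood of series sharing one latent GP mean.

    Equivalent to the zero-mean multivariate normal over the stacked n*T
    observations with covariance Cov(y_ai, y_bj) = k_SE(t_i, t_j) +
    sigma_n^2 * delta_ab * delta_ij, evaluated via a T x T Cholesky
    factorization.
    """
    Y = np.atleast_2d(np.asarray(members, dtype=float))
    if Y.shape[1] != len(np.asarray(t)):
        raise ValueError("member series length must match the time grid")
    cache = _MarginalCache(t, hp)
    return cache.logmarg(Y.shape[0], Y.sum(axis=0), float((Y ** 2).sum()))


class _ClusterState:
    __slots__ = ("n", "ysum", "ysumsq", "logmarg")

    def __init__(self, n, ysum, ysumsq, logmarg):
        self.n = n
        self.ysum = ysum
        self.ysumsq = ysumsq
        self.logmarg = logmarg


def dpgp_cluster(members, t, alpha: float = 1.0,
                 max_num_iterations: int = 1000, burn_frac: float = 0.5,
                 seed: int = 0, hp: GPHyperparams | None = None,
                 parent_cluster: int = 0,
                 thin: int = 1) -> FineClustering:
    """Collapsed-Gibbs DP-GP sub-clustering of one parent cluster.

    Parameters
    ----------
    members : array-like (n, T) or list of Trajectory-like with ``.y``
    t : time grid (hours)
    alpha : CRP concentration
    max_num_iterations : number of Gibbs sweeps
    burn_frac : fraction of sweeps discarded before accumulating the
        co-clustering similarity matrix
    thin : record every ``thin``-th post-burn-in sweep
    """
    if max_num_iterations < 1:
        raise ValueError("max_num_iterations must be >= 1")
    if not 0 <= burn_frac < 1:
        raise ValueError("burn_frac must be in [0, 1)")
    Y = np.asarray([getattr(m, "y", m) for m in members], dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("members must be a nonempty set of equal-length series")
    n, T = Y.shape
    t = np.asarray(t, dtype=float)
    if hp is None:
        hp = estimate_hyperparams(Y, t)
    cache = _MarginalCache(t, hp)
    ysq = (Y ** 2).sum(axis=1)

    if n == 1:
        return FineClustering(parent_cluster, np.zeros(1, dtype=int),
                              np.ones((1, 1)), max_num_iterations, alpha, seed)

    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    clusters: dict[int, _ClusterState] = {}

    def make_cluster(idx):
        mask = labels == idx
        cnt = int(mask.sum())
        ysum = Y[mask].sum(axis=0)
        ysumsq = float(ysq[mask].sum())
        clusters[idx] = _ClusterState(cnt, ysum, ysumsq,
                                      cache.logmarg(cnt, ysum, ysumsq))

    make_cluster(0)
    next_label = 1

    burn = int(math.floor(burn_frac * max_num_iterations))
    co = np.zeros((n, n))
    n_rec = 0
    sampled: list[np.ndarray] = []
    log_alpha = math.log(alpha)

    for sweep in range(max_num_iterations):
        for i in range(n):
            lab = labels[i]
            st = clusters[lab]
            # remove point i from its cluster
            if st.n == 1:
                del clusters[lab]
            else:
                st.n -= 1
                st.ysum = st.ysum - Y[i]
                st.ysumsq -= float(ysq[i])
                st.logmarg = cache.logmarg(st.n, st.ysum, st.ysumsq)
            keys = list(clusters.keys())
            logw = np.empty(len(keys) + 1)
            for ci, key in enumerate(keys):
                c = clusters[key]
                lm_new = cache.logmarg(c.n + 1, c.ysum + Y[i],
                                       c.ysumsq + float(ysq[i]))
                logw[ci] = math.log(c.n) + lm_new - c.logmarg
            single = cache.logmarg(1, Y[i], float(ysq[i]))
            logw[-1] = log_alpha + single
            logw -= logw.max()
            w = np.exp(logw)
            choice = rng.choice(len(w), p=w / w.sum())
            if choice == len(keys):
                labels[i] = next_label
                clusters[next_label] = _ClusterState(1, Y[i].copy(),
                                                     float(ysq[i]), single)
                next_label += 1
            else:
                key = keys[choice]
                c = clusters[key]
                labels[i] = key
                c.n += 1
                c.ysum = c.ysum + Y[i]
                c.ysumsq += float(ysq[i])
                c.logmarg = cache.logmarg(c.n, c.ysum, c.ysumsq)
        if sweep >= burn and (sweep - burn) % thin == 0:
            co += labels[:, None] == labels[None, :]
            n_rec += 1
            sampled.append(labels.copy())

    if n_rec == 0:  # burn consumed everything; keep the final state
        co += labels[:, None] == labels[None, :]
        n_rec = 1
        sampled.append(labels.copy())
    sim = co / n_rec
    np.fill_diagonal(sim, 1.0)

    # least-squares partition: sampled partition closest to the similarity
    best_idx, best_loss = 0, np.inf
    for idx, part in enumerate(sampled):
        same = (part[:, None] == part[None, :]).astype(float)
        loss = float(((same - sim) ** 2).sum())
        if loss < best_loss:
            best_idx, best_loss = idx, loss
    final = sampled[best_idx]
    # relabel contiguous from 0 in order of first appearance
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(final):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return FineClustering(parent_cluster, out, sim, max_num_iterations,
                          alpha, seed)
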