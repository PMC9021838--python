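"""Soft dynamic time warping (soft-DTW) loss, barycenters and K-means.

Soft-DTW replaces the hard minimum in the classic DTW recursion with the
smooth soft-minimum

    softmin_gamma(v_1..v_p) = -gamma * log sum_i exp(-v_i / gamma),

so the resulting alignment cost is differentiable in both inputs and equals
-gamma * log of the sum over all monotone alignment paths of
exp(-cost(path)/gamma). As gamma -> 0 it recovers classic DTW. The ground
cost per aligned pair is the squared difference.

K-means under this loss alternates nearest-centroid assignment with a
barycenter update, where the barycenter of a set of series is the local
minimizer of the summed soft-DTW to its members, found by gradient descent
with a backtracking line search (the soft-DTW gradient comes from the
standard forward/backward pass over the alignment lattice).

All heavy paths are batched over pairs with NumPy; series here are short
(one value per time point of the experiment), so the T x T lattice loops
are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gem import Trajectory

__all__ = [
    "soft_min",
    "soft_dtw",
    "soft_dtw_pairwise",
    "sdtw_barycenter",
    "sdtw_kmeans",
    "InitialClustering",
]


def soft_min(values, gamma: float) -> float:
    """Soft minimum -gamma*log(sum exp(-v/gamma)); +inf entries drop out."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("soft_min of an empty collection")
    m = v.min()
    if np.isinf(m):
        return float("inf")
    s = np.exp(-(v[np.isfinite(v)] - m) / gamma).sum()
    return float(m - gamma * np.log(s))


def _softmin3(a, b, c, gamma):
    """Elementwise soft-min of three arrays, tolerating +inf entries."""
    m = np.minimum(np.minimum(a, b), c)
    finite = np.isfinite(m)
    # where m is +inf all three are +inf; keep +inf there
    out = np.array(m, dtype=float, copy=True)
    if np.any(finite):
        ea = np.where(np.isinf(a), -np.inf, -(a - m))
        eb = np.where(np.isinf(b), -np.inf, -(b - m))
        ec = np.where(np.isinf(c), -np.inf, -(c - m))
        s = np.exp(ea / gamma) + np.exp(eb / gamma) + np.exp(ec / gamma)
        out = np.where(finite, m - gamma * np.log(s), out)
    return out


def _forward(D, gamma):
    """Batched soft-DTW forward pass.

    D : (..., n, m) ground-cost lattice. Returns R of shape
    (..., n+1, m+1) with R[..., n, m] the soft-DTW value.
    """
    *lead, n, m = D.shape
    R = np.full((*lead, n + 1, m + 1), np.inf)
    R[..., 0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            R[..., i, j] = D[..., i - 1, j - 1] + _softmin3(
                R[..., i - 1, j - 1], R[..., i - 1, j], R[..., i, j - 1], gamma
            )
    return R


def soft_dtw(x, y, gamma: float = 1.0) -> float:
    """Soft-DTW discrepancy between two 1-D series (squared-difference cost)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("soft_dtw of an empty series")
    D = (x[:, None] - y[None, :]) ** 2
    return float(_forward(D, gamma)[-1, -1])


def soft_dtw_pairwise(X, Y, gamma: float = 1.0) -> np.ndarray:
    """All-pairs soft-DTW between rows of X (N,Tx) and rows of Y (M,Ty)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D (series x time)")
    # D[nm-pair, i, j] = (X[n,i] - Y[m,j])^2
    D = (X[:, None, :, None] - Y[None, :, None, :]) ** 2
    return _forward(D, gamma)[..., -1, -1]


def _grad_wrt_first(b, Y, gamma):
    """Value and gradient of sum_s soft_dtw(b, Y[s]) with respect to b.

    Standard soft-DTW backward pass: E[i, j] is the expected alignment
    weight of lattice cell (i, j) under the Gibbs distribution over paths.
    """
    b = np.asarray(b, dtype=float)
    Y = np.asarray(Y, dtype=float)
    S, m = Y.shape
    n = b.size
    D = (b[None, :, None] - Y[:, None, :]) ** 2  # (S, n, m)
    R = _forward(D, gamma)  # (S, n+1, m+1)
    value = float(R[:, -1, -1].sum())

    # padded arrays for the backward recursion
    Dp = np.zeros((S, n + 2, m + 2))
    Dp[:, 1:n + 1, 1:m + 1] = D
    Rp = np.full((S, n + 2, m + 2), -np.inf)
    Rp[:, :n + 1, :m + 1] = R
    Rp[:, n + 1, m + 1] = R[:, n, m]
    E = np.zeros((S, n + 2, m + 2))
    E[:, n + 1, m + 1] = 1.0
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n, 0, -1):
            for j in range(m, 0, -1):
                a = np.exp((Rp[:, i + 1, j] - Rp[:, i, j] - Dp[:, i + 1, j]) / gamma)
                bb = np.exp((Rp[:, i, j + 1] - Rp[:, i, j] - Dp[:, i, j + 1]) / gamma)
                c = np.exp(
                    (Rp[:, i + 1, j + 1] - Rp[:, i, j] - Dp[:, i + 1, j + 1]) / gamma
                )
                E[:, i, j] = (E[:, i + 1, j] * np.nan_to_num(a)
                              + E[:, i, j + 1] * np.nan_to_num(bb)
                              + E[:, i + 1, j + 1] * np.nan_to_num(c))
    Ein = E[:, 1:n + 1, 1:m + 1]  # (S, n, m)
    diff = b[None, :, None] - Y[:, None, :]
    grad = 2.0 * (Ein * diff).sum(axis=(0, 2))
    return value, grad


def sdtw_barycenter(series_list, gamma: float = 1.0, init=None,
                    max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Length-T series locally minimizing the summed soft-DTW to the members.

    Gradient descent from ``init`` (default: the Euclidean mean) with
    backtracking line search, so the objective is non-increasing across
    iterations; stops at ``max_iter`` or when the relative improvement
    drops below ``tol``.
    """
    Y = np.asarray(series_list, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("series_list must be a nonempty list of equal-length series")
    b = np.array(Y.mean(axis=0) if init is None else init, dtype=float)
    f, g = _grad_wrt_first(b, Y, gamma)
    step = 1.0 / max(1, Y.shape[0])
    for _ in range(max_iter):
        gnorm = np.linalg.norm(g)
        if gnorm == 0:
            break
        improved = False
        s = step
        for _ in range(30):
            b_new = b - s * g
            f_new, g_new = _grad_wrt_first(b_new, Y, gamma)
            if f_new < f:
                improved = True
                break
            s *= 0.5
        if not improved:
            break
        rel = (f - f_new) / max(abs(f), 1e-12)
        b, f, g = b_new, f_new, g_new
        step = min(s * 2.0, 1e6)
        if rel < tol:
            break
    return b


@dataclass
class InitialClustering:
    """Result of the coarse soft-DTW K-means pass."""

    k: int
    assignment: np.ndarray          # cluster index per trajectory
    centroids: np.ndarray           # (k, T) barycenter series
    inertia: float                  # sum of soft-DTW of members to centroid
    gamma: float
    seed: int
    n_iter: int = 0
    inertia_history: list = None

    def __post_init__(self):
        if not np.isfinite(self.inertia):
            raise ValueError("inertia must be finite")


def _traj_matrix(trajs) -> np.ndarray:
    rows = []
    for tr in trajs:
        rows.append(tr.y if isinstance(tr, Trajectory) else np.asarray(tr, float))
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2:
        raise ValueError("all trajectories must share one length")
    return X


def _plusplus_init(X, k, rng):
    """k-means++ D^2 seeding on the raw series (Euclidean surrogate).

    Spreads the initial centroids over distinct trajectory shapes, which
    makes restarts far less likely to land in local optima than uniform
    sampling; the Lloyd iterations that follow use the soft-DTW loss.
    """
    N = X.shape[0]
    centroids = [X[rng.integers(N)]]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids.append(X[rng.integers(N)])
            continue
        nxt = rng.choice(N, p=d2 / total)
        centroids.append(X[nxt])
        d2 = np.minimum(d2, ((X - centroids[-1]) ** 2).sum(axis=1))
    return np.array(centroids, dtype=float)


def sdtw_kmeans(trajs, k: int, gamma: float = 1.0, seed: int = 0,
                n_init: int = 5, max_iter: int = 50,
                init_centroids=None) -> InitialClustering:
    """K-means under the soft-DTW loss over pooled per-replicate trajectories.

    Both conditions and all replicates are clustered together so that the
    cluster labels form one shared space in which control and treated
    profiles can be compared. Assignment uses the nearest centroid under
    soft-DTW; the centroid update is the soft-DTW barycenter. Empty clusters
    are reseeded with the trajectory farthest from its current centroid.
    Best of ``n_init`` random restarts; deterministic given ``seed``.
    """
    X = _traj_matrix(trajs)
    N = X.shape[0]
    if k < 1 or k > N:
        raise ValueError(f"k={k} must be in [1, {N}]")
    rng = np.random.default_rng(seed)
    best = None
    restarts = 1 if init_centroids is not None else max(1, n_init)
    for _ in range(restarts):
        if init_centroids is not None:
            C = np.array(init_centroids, dtype=float)
            if C.shape != (k, X.shape[1]):
                raise ValueError("init_centroids must have shape (k, T)")
        else:
            C = _plusplus_init(X, k, rng)
        assign = np.full(N, -1, dtype=int)
        history = []
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            dist = soft_dtw_pairwise(X, C, gamma)  # (N, k)
            new_assign = dist.argmin(axis=1)
            # empty-cluster repair: reseed with the worst-fit trajectory,
            # never stealing a point that was itself just used for repair
            repaired: set[int] = set()
            for c in range(k):
                if not np.any(new_assign == c):
                    fit = dist[np.arange(N), new_assign].copy()
                    # avoid emptying another cluster or reusing a repair point
                    for idx in repaired:
                        fit[idx] = -np.inf
                    sizes = np.bincount(new_assign, minlength=k)
                    fit[sizes[new_assign] <= 1] = -np.inf
                    worst = int(fit.argmax())
                    new_assign[worst] = c
                    repaired.add(worst)
            inertia = float(dist[np.arange(N), new_assign].sum())
            history.append(inertia)
            if np.array_equal(new_assign, assign):
                assign = new_assign
                break
            assign = new_assign
            for c in range(k):
                members = X[assign == c]
                if len(members):
                    C[c] = sdtw_barycenter(members, gamma=gamma, init=C[c],
                                           max_iter=20, tol=1e-5)
        dist = soft_dtw_pairwise(X, C, gamma)
        inertia = float(dist[np.arange(N), assign].sum())
        if best is None or inertia < best.inertia:
            best = InitialClustering(k=k, assignment=assign.copy(),
                                     centroids=C.copy(), inertia=inertia,
                                     gamma=gamma, seed=seed, n_iter=n_iter,
                                     inertia_history=history)
    return best
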