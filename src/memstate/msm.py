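"""Clustering and reversible Markov state model estimation.

tIC-space frames are discretised with mini-batch k-means; transition
counts at the MSM lag (default 4.5 ns) are restricted to the largest
strongly connected set of states, and the transition matrix is the
maximum-likelihood estimate under detailed balance, obtained by the
classic self-consistent iteration on symmetrized pair counts.  The
stationary distribution of the reversible matrix supplies equilibrium
frame weights for free-energy landscapes estimated from many short,
arbitrarily initialised trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

DEFAULT_MSM_LAG = 4.5  # ns


@dataclass
class ClusterModel:
    centers: np.ndarray  # (k, dim)
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape[0] < 2:
            raise ValueError("clustering requires k >= 2")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("cluster centers must be finite")

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def fit_minibatch_kmeans(tics: list[np.ndarray], k: int, seed: int = 0,
                         batch_size: int = 1024, n_iter: int = 200) -> ClusterModel:
    """Mini-batch k-means over the pooled tIC frames (deterministic per seed)."""
    from sklearn.cluster import MiniBatchKMeans

    x = np.concatenate([np.asarray(t, dtype=float) for t in tics], axis=0)
    if len(x) < k:
        raise ValueError(f"{len(x)} frames cannot support k={k} clusters")
    distinct = np.unique(x, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(f"k={k} exceeds the {distinct.shape[0]} distinct points")
    if k == distinct.shape[0]:  # every distinct point is its own center
        return ClusterModel(distinct, seed=seed, inertia=0.0)
    km = MiniBatchKMeans(
        n_clusters=k,
        random_state=seed,
        batch_size=batch_size,
        max_iter=n_iter,
        n_init=3,
    ).fit(x)
    return ClusterModel(km.cluster_centers_, seed=seed, inertia=float(km.inertia_))


def assign(model: ClusterModel, tics: list[np.ndarray]) -> list[np.ndarray]:
    """Nearest-center state sequences; ties break to the lowest index."""
    out = []
    for t in tics:
        t = np.atleast_2d(np.asarray(t, dtype=float))
        if t.shape[1] != model.centers.shape[1]:
            raise ValueError("tIC dimension does not match cluster centers")
        d = cdist(t, model.centers)
        out.append(np.argmin(d, axis=1).astype(np.int64))  # argmin -> first (lowest) index
    return out


def count_transitions(states: list[np.ndarray], lag_time: float, frame_interval: float,
                      n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    The lag is rounded down to an integer number of frames when it is
    not an exact multiple of the frame interval (logged); counting
    never crosses trajectory boundaries.
    """
    lag = int(lag_time / frame_interval + 1e-9)
    if abs(lag * frame_interval - lag_time) > 1e-9:
        logger.info("MSM lag %.4g ns rounded down to %d frames", lag_time, lag)
    if lag < 1:
        raise ValueError("lag time is below one frame interval")
    if n_states is None:
        n_states = int(max(int(np.max(s)) for s in states if len(s))) + 1
    c = np.zeros((n_states, n_states))
    counted = False
    for s in states:
        s = np.asarray(s, dtype=np.int64)
        if len(s) <= lag:
            continue
        counted = True
        np.add.at(c, (s[:-lag], s[lag:]), 1.0)
    if not counted:
        raise ValueError("every trajectory is shorter than the MSM lag")
    return c


def largest_connected_set(c: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph."""
    c = np.asarray(c)
    if np.any(c < 0):
        raise ValueError("count matrix must be nonnegative")
    if not np.any(c > 0):
        raise ValueError("empty count matrix: no transitions observed")
    n, labels = connected_components(csr_matrix(c > 0), directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n)
    best = int(np.argmax(sizes))  # ties resolve to the lowest label (first-seen)
    active = np.nonzero(labels == best)[0]
    dropped = c.shape[0] - active.size
    if dropped:
        logger.info("ergodic trimming dropped %d of %d states", dropped, c.shape[0])
    return active


@dataclass
class MSMModel:
    """Reversible MSM on the active (ergodically connected) state set."""

    lag_time: float  # ns
    counts: np.ndarray  # raw counts restricted to the active set
    active_set: np.ndarray  # active index -> original state label
    n_states_full: int
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray  # descending, lambda_1 = 1
    right_eigenvectors: np.ndarray
    left_eigenvectors: np.ndarray
    full_to_active: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = np.full(self.n_states_full, -1, dtype=np.int64)
        m[self.active_set] = np.arange(self.active_set.size)
        self.full_to_active = m

    @property
    def n_states(self) -> int:
        return self.active_set.size

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            for k in ("counts", "active_set", "transition_matrix",
                      "stationary_distribution", "eigenvalues",
                      "right_eigenvectors", "left_eigenvectors"):
                h.create_dataset(k, data=getattr(self, k))
            h.attrs["lag_time"] = self.lag_time
            h.attrs["n_states_full"] = self.n_states_full

    @classmethod
    def load_hdf5(cls, path) -> "MSMModel":
        import h5py

        with h5py.File(path, "r") as h:
            data = {k: h[k][:] for k in ("counts", "active_set", "transition_matrix",
                                         "stationary_distribution", "eigenvalues",
                                         "right_eigenvectors", "left_eigenvectors")}
            return cls(lag_time=float(h.attrs["lag_time"]),
                       n_states_full=int(h.attrs["n_states_full"]), **data)


def _reversible_mle(c: np.ndarray, tol: float = 1e-10, max_iter: int = 1_000_000):
    """Self-consistent iteration for the detailed-balance MLE.

    Maximises the likelihood over reversible transition matrices via the
    fixed point x_ij = (c_ij + c_ji) / (c_i/x_i + c_j/x_j); returns the
    symmetric flux matrix x (normalised) whose row sums give pi.
    """
    c = np.asarray(c, dtype=float)
    c_row = c.sum(axis=1)
    if np.any(c_row <= 0):
        raise ValueError("every active state needs at least one outgoing count")
    csym = c + c.T
    mask = csym > 0
    x = csym / csym.sum()
    t_prev = x / x.sum(axis=1, keepdims=True)
    for it in range(max_iter):
        xi = x.sum(axis=1)
        denom = c_row[:, None] / xi[:, None] + c_row[None, :] / xi[None, :]
        x = np.where(mask, csym / np.where(mask, denom, 1.0), 0.0)
        t = x / x.sum(axis=1, keepdims=True)
        resid = np.max(np.abs(t - t_prev))
        if resid < tol:
            return x / x.sum(), it + 1
        t_prev = t
    raise RuntimeError(
        f"reversible MLE did not converge in {max_iter} iterations "
        f"(residual {resid:.2e})"
    )


def fit_reversible_msm(counts: np.ndarray, lag_time: float,
                       active_set: np.ndarray | None = None,
                       n_states_full: int | None = None,
                       tol: float = 1e-10) -> MSMModel:
    """Maximum-likelihood reversible MSM from an active-set count matrix."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if active_set is None:
        active_set = np.arange(n)
    if n_states_full is None:
        n_states_full = int(np.max(active_set)) + 1 if n else 0
    x, _ = _reversible_mle(counts, tol=tol)
    pi = x.sum(axis=1)
    t = x / pi[:, None]
    sq = np.sqrt(pi)
    m = (sq[:, None] * t) / sq[None, :]
    m = 0.5 * (m + m.T)
    w, phi = scipy.linalg.eigh(m)
    order = np.argsort(w)[::-1]
    w = w[order]
    phi = phi[:, order]
    right = phi / sq[:, None]
    left = phi * sq[:, None]
    # fix sign so the stationary eigenvector is positive
    for j in range(right.shape[1]):
        i = int(np.argmax(np.abs(right[:, j])))
        if right[i, j] < 0:
            right[:, j] = -right[:, j]
            left[:, j] = -left[:, j]

    assert np.max(np.abs(t.sum(axis=1) - 1.0)) < 1e-12, "rows must sum to 1"
    db = pi[:, None] * t - (pi[:, None] * t).T
    assert np.max(np.abs(db)) < 1e-10, "detailed balance violated"
    assert abs(pi.sum() - 1.0) < 1e-12
    assert abs(w[0] - 1.0) < 1e-8, "leading eigenvalue must be 1"
    assert np.max(np.abs(pi @ t - pi)) < 1e-10, "pi must be stationary"

    return MSMModel(
        lag_time=lag_time,
        counts=counts,
        active_set=np.asarray(active_set, dtype=np.int64),
        n_states_full=int(n_states_full),
        transition_matrix=t,
        stationary_distribution=pi,
        eigenvalues=w,
        right_eigenvectors=right,
        left_eigenvectors=left,
    )


def estimate_msm(states: list[np.ndarray], lag_time: float, frame_interval: float,
                 n_states: int | None = None) -> MSMModel:
    """Count, ergodically trim, and fit a reversible MSM in one call."""
    c = count_transitions(states, lag_time, frame_interval, n_states=n_states)
    active = largest_connected_set(c)
    sub = c[np.ix_(active, active)]
    return fit_reversible_msm(sub, lag_time, active_set=active, n_states_full=c.shape[0])


def implied_timescales(msm: MSMModel, n: int) -> np.ndarray:
    """Relaxation times ``-tau / ln(lambda_{i+1})`` in ns (nan if undefined)."""
    out = np.full(n, np.nan)
    for i in range(n):
        if i + 1 >= msm.eigenvalues.size:
            break
        lam = msm.eigenvalues[i + 1]
        if lam <= 0 or lam >= 1:
            logger.info("implied timescale %d undefined (eigenvalue %.4g)", i + 2, lam)
            continue
        out[i] = -msm.lag_time / np.log(lam)
    return out


def stationary_frame_weights(msm: MSMModel, states: list[np.ndarray]) -> list[np.ndarray]:
    """Per-frame equilibrium weights ``pi_s / n_s`` (0 outside the active set)."""
    concat = np.concatenate([np.asarray(s, dtype=np.int64) for s in states])
    act = msm.full_to_active[concat]
    inside = act >= 0
    n_s = np.bincount(act[inside], minlength=msm.n_states).astype(float)
    w = np.zeros(concat.size)
    w[inside] = msm.stationary_distribution[act[inside]] / n_s[act[inside]]
    dropped = int((~inside).sum())
    if dropped:
        logger.info("%d frames outside the active set carry zero weight", dropped)
    out, i = [], 0
    for s in states:
        out.append(w[i:i + len(s)])
        i += len(s)
    return out
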