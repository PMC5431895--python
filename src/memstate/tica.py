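"""Time-lagged independent component analysis with ridge regularization.

tICA finds the most slowly decorrelating linear combinations of
features by solving the generalized symmetric eigenproblem

    Cbar v = lambda (C00 + g I) v

where ``Cbar`` is the symmetrized time-lagged covariance and ``C00``
the instantaneous covariance, both estimated over the union of the
lagged windows of every trajectory (lagged pairs never cross trajectory
boundaries).  Estimating ``C00`` over the same windows as ``Cbar``
bounds every eigenvalue by 1 in magnitude; the ridge term ``g I``
("L2 regularization strength") shrinks eigenvalues and regularizes
near-singular feature covariances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .featurize import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class TICAModel:
    lag_time: float  # ns
    gamma: float
    mean: np.ndarray
    c00: np.ndarray
    cbar: np.ndarray  # symmetrized time-lagged covariance
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # (n_features, n_components), columns are eigenvectors
    n_components: int
    labels: list[str] | None = None

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            for k in ("mean", "c00", "cbar", "eigenvalues", "components"):
                h.create_dataset(k, data=getattr(self, k))
            h.attrs["lag_time"] = self.lag_time
            h.attrs["gamma"] = self.gamma
            h.attrs["n_components"] = self.n_components

    @classmethod
    def load_hdf5(cls, path) -> "TICAModel":
        import h5py

        with h5py.File(path, "r") as h:
            data = {k: h[k][:] for k in ("mean", "c00", "cbar", "eigenvalues", "components")}
            return cls(
                lag_time=float(h.attrs["lag_time"]),
                gamma=float(h.attrs["gamma"]),
                n_components=int(h.attrs["n_components"]),
                **data,
            )


def _as_arrays(features) -> tuple[list[np.ndarray], float, list[str] | None]:
    arrays, fi, labels = [], None, None
    for f in features:
        if isinstance(f, FeatureMatrix):
            arrays.append(f.values)
            fi = f.frame_interval
            labels = f.labels
        else:
            arrays.append(np.asarray(f, dtype=float))
    return arrays, fi, labels


def fit_tica(features, lag_time: float, gamma: float, n_components: int = 4,
             frame_interval: float | None = None) -> TICAModel:
    """Estimate a tICA model from pooled trajectories.

    ``features`` is a list of :class:`FeatureMatrix` (or plain arrays
    with ``frame_interval`` given).  The lag is rounded to the nearest
    integer multiple of the frame interval (logged when rounding
    changes it); trajectories shorter than the lag contribute nothing.
    """
    arrays, fi, labels = _as_arrays(features)
    fi = frame_interval if frame_interval is not None else fi
    if fi is None:
        raise ValueError("frame_interval is required when passing raw arrays")
    lag = int(round(lag_time / fi))
    if abs(lag * fi - lag_time) > 1e-9:
        logger.info("tICA lag %.4g ns rounded to %d frames (%.4g ns)", lag_time, lag, lag * fi)
    if lag < 1:
        raise ValueError(f"lag time {lag_time} ns is below one frame interval ({fi} ns)")

    dim = arrays[0].shape[1]
    s_x = np.zeros(dim)
    s_xx = np.zeros((dim, dim))
    s_xy = np.zeros((dim, dim))
    n_pairs = 0
    for a in arrays:
        if len(a) <= lag:
            logger.warning("trajectory with %d frames shorter than lag %d; skipped", len(a), lag)
            continue
        x, y = a[:-lag], a[lag:]
        s_x += x.sum(axis=0) + y.sum(axis=0)
        s_xx += x.T @ x + y.T @ y
        s_xy += x.T @ y
        n_pairs += len(x)
    if n_pairs == 0:
        raise ValueError("no trajectory is longer than the tICA lag")

    mean = s_x / (2 * n_pairs)
    c00 = s_xx / (2 * n_pairs) - np.outer(mean, mean)
    c0t = s_xy / n_pairs - np.outer(mean, mean)
    cbar = 0.5 * (c0t + c0t.T)

    var = np.diag(c00)
    dead = np.nonzero(var < 1e-12)[0]
    if dead.size:
        names = [labels[i] if labels else str(i) for i in dead]
        raise ValueError(f"constant feature column(s): {names}; remove before tICA")

    w, v = scipy.linalg.eigh(cbar, c00 + gamma * np.eye(dim))
    order = np.argsort(w)[::-1][:n_components]
    w = w[order]
    v = v[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    if np.max(np.abs(w)) > 1.0 + 1e-8:
        logger.warning("tICA eigenvalue magnitude exceeds 1: %s", w)
    return TICAModel(
        lag_time=lag * fi,
        gamma=gamma,
        mean=mean,
        c00=c00,
        cbar=cbar,
        eigenvalues=w,
        components=v,
        n_components=n_components,
        labels=labels,
    )


def transform(model: TICAModel, features) -> np.ndarray:
    """Project one feature matrix onto the tICA components."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.ndim != 2 or x.shape[1] != model.mean.size:
        raise ValueError(
            f"feature dimension {x.shape} does not match model dimension {model.mean.size}"
        )
    return (x - model.mean) @ model.components


def transform_all(model: TICAModel, features: list) -> list[np.ndarray]:
    return [transform(model, f) for f in features]
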