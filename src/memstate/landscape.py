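"""Depth/angle collective variables and free-energy landscapes.

The peptide's membrane position is summarised by two collective
variables: the signed distance ``d`` of the binding-site centroid (mean
of the M9/T12/L21/V25 alpha carbons) from the membrane-center plane,
and the tilt angle ``theta`` between the membrane plane and the body
axis drawn from that centroid to the centroid of the F3/G35/N48 alpha
carbons and the zinc.  Equilibrium populations come from the MSM
stationary distribution: each frame carries weight ``pi_s / n_s`` for
its state, the weighted 2-D histogram gives ``F = -kT ln p``, and basin
free-energy differences follow as ``dG = -kT ln(P_shallow / P_deep)``
with trajectory-bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .embed import BINDING_RESIDUES, DISTAL_RESIDUES
from .msm import MSMModel, estimate_msm, stationary_frame_weights
from .synthetic import KT_300K, CVTrajectorySet
from .systems import Topology, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class CVSeries:
    """Per-frame (d, theta) plus the membrane reference planes (one trajectory)."""

    d: np.ndarray  # nm, signed from the membrane-center plane
    theta: np.ndarray  # degrees, in [-90, 90]
    z_center: np.ndarray  # nm per frame
    bottom_leaflet_z: np.ndarray  # nm per frame
    frame_interval: float  # ns

    def __post_init__(self) -> None:
        for name in ("d", "theta", "z_center", "bottom_leaflet_z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if np.any(np.abs(self.theta) > 90.0 + 1e-9):
            raise ValueError("theta must lie in [-90, 90] degrees")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.d, self.theta])


@dataclass(frozen=True)
class BasinDefinition:
    """Named rectangular (d, theta) regions for the deep and shallow states."""

    deep: tuple[float, float, float, float]  # (d_min, d_max, theta_min, theta_max)
    shallow: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for rect in (self.deep, self.shallow):
            if rect[0] >= rect[1] or rect[2] >= rect[3]:
                raise ValueError("basin rectangles must have positive extent")
        a, b = self.deep, self.shallow
        if (a[0] < b[1] and b[0] < a[1]) and (a[2] < b[3] and b[2] < a[3]):
            raise ValueError("deep and shallow basins must be disjoint")

    def contains(self, points: np.ndarray, which: str) -> np.ndarray:
        r = getattr(self, which)
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= r[0]) & (p[:, 0] < r[1]) & (p[:, 1] >= r[2]) & (p[:, 1] < r[3])
        )


# ---------------------------------------------------------------------------
# Membrane frame and collective variables
# ---------------------------------------------------------------------------


def _two_means_1d(z: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Exact 1-D 2-means: optimal split of sorted values by within-class SSE."""
    order = np.argsort(z)
    zs = z[order]
    n = len(zs)
    c1 = np.cumsum(zs)
    c2 = np.cumsum(zs**2)
    k = np.arange(1, n)
    sse_lo = c2[k - 1] - c1[k - 1] ** 2 / k
    sse_hi = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    split = int(k[np.argmin(sse_lo + sse_hi)])
    m_lo = c1[split - 1] / split
    m_hi = (c1[-1] - c1[split - 1]) / (n - split)
    labels = np.empty(n, dtype=bool)
    labels[order[:split]] = False
    labels[order[split:]] = True  # True = upper leaflet
    return m_lo, m_hi, labels


def compute_membrane_frame(traj: Trajectory, topo: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame membrane-center plane and peptide-proximal leaflet plane.

    Leaflets are separated by (exact 1-D) 2-means on phosphorus z; the
    center is the midpoint of the two leaflet mean planes and the
    "bottom" leaflet is the one nearer the peptide centroid.
    """
    lip = topo.lipid_phosphorus
    if lip.size < 2:
        raise ValueError("need phosphorus atoms in both leaflets")
    pep = np.concatenate([topo.protein_heavy, topo.zinc])
    z_center = np.empty(traj.n_frames)
    bottom = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        z = traj.xyz[f, lip, 2]
        m_lo, m_hi, labels = _two_means_1d(z)
        s_lo = z[~labels].std() if (~labels).sum() > 1 else 0.0
        s_hi = z[labels].std() if labels.sum() > 1 else 0.0
        if abs(m_hi - m_lo) < 3.0 * max(s_lo, s_hi, 1e-12):
            raise ValueError(
                f"leaflet separation ambiguous at frame {f}: means {m_lo:.3f}/{m_hi:.3f} nm "
                f"overlap within the cluster spread"
            )
        zc = 0.5 * (m_lo + m_hi)
        pz = traj.xyz[f, pep, 2].mean()
        z_center[f] = zc
        bottom[f] = m_hi if abs(pz - m_hi) < abs(pz - m_lo) else m_lo
    return z_center, bottom


def compute_cv(traj: Trajectory, topo: Topology) -> CVSeries:
    """Depth and tilt angle of the peptide relative to the membrane.

    ``d`` is the signed distance of the binding-site centroid from the
    membrane-center plane, positive toward the peptide-proximal leaflet
    and beyond; ``theta`` is the angle of the binding-to-distal body
    axis out of the membrane plane, positive when the distal end points
    away from the membrane.
    """
    missing = []
    ca = {}
    for r in BINDING_RESIDUES + DISTAL_RESIDUES:
        try:
            ca[r] = topo.alpha_carbon(r)
        except KeyError:
            missing.append(f"CA of residue {r}")
    zn = topo.zinc
    if zn.size != 1:
        missing.append("zinc")
    if missing:
        raise ValueError(f"missing atoms required for the collective variables: {missing}")

    z_center, bottom = compute_membrane_frame(traj, topo)
    bind = traj.xyz[:, [ca[r] for r in BINDING_RESIDUES], :].mean(axis=1)
    distal_pts = np.concatenate(
        [traj.xyz[:, [ca[r] for r in DISTAL_RESIDUES], :], traj.xyz[:, zn, :]], axis=1
    )
    distal = distal_pts.mean(axis=1)
    sign = np.where(bottom > z_center, 1.0, -1.0)
    d = sign * (bind[:, 2] - z_center)
    axis = distal - bind
    sin_t = sign * axis[:, 2] / np.linalg.norm(axis, axis=1)
    theta = np.degrees(np.arcsin(np.clip(sin_t, -1.0, 1.0)))
    return CVSeries(d, theta, z_center, bottom, traj.frame_interval)


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyLandscape:
    """2-D free-energy surface F(d, theta) with its probability masses."""

    d_edges: np.ndarray
    theta_edges: np.ndarray
    p: np.ndarray  # (n_d, n_theta), sums to 1 over occupied bins
    kT: float

    @property
    def free_energy(self) -> np.ndarray:
        """``-kT ln p`` shifted so the minimum is 0; empty bins are NaN."""
        with np.errstate(divide="ignore"):
            f = np.where(self.p > 0, -self.kT * np.log(self.p), np.nan)
        return f - np.nanmin(f)

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def to_csv(self, path) -> None:
        import pandas as pd

        dd, tt = np.meshgrid(self.d_centers, self.theta_centers, indexing="ij")
        f = self.free_energy
        pd.DataFrame(
            {
                "d_center_nm": dd.ravel(),
                "theta_center_deg": tt.ravel(),
                "F_kcal_mol": f.ravel(),
                "p": self.p.ravel(),
            }
        ).to_csv(path, index=False, float_format="%.10g")

    def plot(self, ax=None, levels: int = 20):
        """Render a heatmap (kcal/mol); returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = np.ma.masked_invalid(self.free_energy)
        mesh = ax.pcolormesh(self.d_edges, self.theta_edges, f.T, shading="auto")
        ax.figure.colorbar(mesh, ax=ax, label="F (kcal/mol)")
        ax.set_xlabel("distance from membrane center (nm)")
        ax.set_ylabel("angle with membrane plane (deg)")
        return ax


def _cv_arrays(cvs) -> list[np.ndarray]:
    if isinstance(cvs, CVTrajectorySet):
        return cvs.trajectories
    out = []
    for c in cvs:
        out.append(c.points if isinstance(c, CVSeries) else np.asarray(c, dtype=float))
    return out


def _edges(points: np.ndarray, bins, pad: float = 0.05):
    if not isinstance(bins, int):
        return np.asarray(bins[0], float), np.asarray(bins[1], float)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - pad * span
    hi = hi + pad * span
    return np.linspace(lo[0], hi[0], bins + 1), np.linspace(lo[1], hi[1], bins + 1)


def _weighted_landscape(points: np.ndarray, weights: np.ndarray, bins, kT) -> FreeEnergyLandscape:
    d_edges, t_edges = _edges(points, bins)
    h, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=(d_edges, t_edges),
                             weights=weights)
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram: no frames fell inside the bin range")
    return FreeEnergyLandscape(d_edges, t_edges, h / total, kT)


def unweighted_histogram(cvs, bins=40, kT: float = KT_300K) -> FreeEnergyLandscape:
    """Raw (equal-frame-weight) free-energy histogram, for comparison."""
    points = np.concatenate(_cv_arrays(cvs), axis=0)
    return _weighted_landscape(points, np.ones(len(points)), bins, kT)


def msm_weighted_histogram(cvs, state_sequences: list[np.ndarray], msm: MSMModel,
                           bins=40, kT: float = KT_300K) -> FreeEnergyLandscape:
    """Equilibrium landscape: frames weighted by ``pi_s / n_s`` of their state.

    Frames assigned to states outside the MSM active set carry zero
    weight (they are logged and effectively dropped).
    """
    arrays = _cv_arrays(cvs)
    points = np.concatenate(arrays, axis=0)
    weights = np.concatenate(stationary_frame_weights(msm, state_sequences))
    if len(weights) != len(points):
        raise ValueError("state sequences and CV series must be frame-aligned")
    return _weighted_landscape(points, weights, bins, kT)


def landscape_l1_error(landscape: FreeEnergyLandscape, reference_p: np.ndarray) -> float:
    """L1 distance between bin mass distributions (reference on the same grid)."""
    return float(np.abs(landscape.p - reference_p).sum())


# ---------------------------------------------------------------------------
# Basin thermodynamics
# ---------------------------------------------------------------------------


@dataclass
class DeltaGResult:
    """Deep/shallow population ratio as a free energy, with bootstrap CI."""

    p_deep: float
    p_shallow: float
    delta_g: float  # kcal/mol; positive = shallow less populated
    kT: float
    basins: BasinDefinition | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    level: float | None = None
    n_replicates: int | None = None
    n_dropped: int = 0
    seed: int | None = None

    @property
    def ci_range(self) -> float | None:
        if self.ci_lower is None:
            return None
        return self.ci_upper - self.ci_lower

    def to_json(self, path=None) -> str:
        payload = {
            "P_deep": self.p_deep,
            "P_shallow": self.p_shallow,
            "delta_G_kcal_mol": self.delta_g,
            "kT_kcal_mol": self.kT,
            "basins": None if self.basins is None else {
                "deep": list(self.basins.deep), "shallow": list(self.basins.shallow)},
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "level": self.level,
            "n_replicates": self.n_replicates,
            "n_dropped": self.n_dropped,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _masses(points: np.ndarray, weights: np.ndarray, basins: BasinDefinition):
    total = weights.sum()
    p_deep = weights[basins.contains(points, "deep")].sum() / total
    p_shallow = weights[basins.contains(points, "shallow")].sum() / total
    return p_deep, p_shallow


def basin_deltaG_from_frames(points: np.ndarray, weights: np.ndarray,
                             basins: BasinDefinition, kT: float = KT_300K,
                             seed: int | None = None) -> DeltaGResult:
    """``dG = -kT ln(P_shallow / P_deep)`` from weighted frames."""
    p_deep, p_shallow = _masses(points, weights, basins)
    if p_deep <= 0 or p_shallow <= 0:
        raise ValueError(
            "a basin holds zero probability mass; widen the basin rectangles "
            f"(P_deep={p_deep:.3g}, P_shallow={p_shallow:.3g})"
        )
    dg = float(-kT * np.log(p_shallow / p_deep))
    return DeltaGResult(float(p_deep), float(p_shallow), dg, kT, basins, seed=seed)


def basin_deltaG(landscape: FreeEnergyLandscape, basins: BasinDefinition) -> DeltaGResult:
    """Basin free-energy difference from a binned landscape's masses."""
    dd, tt = np.meshgrid(landscape.d_centers, landscape.theta_centers, indexing="ij")
    pts = np.column_stack([dd.ravel(), tt.ravel()])
    return basin_deltaG_from_frames(pts, landscape.p.ravel(), basins, landscape.kT)


def delta_delta_G(result_a: DeltaGResult, result_b: DeltaGResult) -> float:
    """``ddG = dG_b - dG_a`` (kcal/mol); both results must share kT."""
    if abs(result_a.kT - result_b.kT) > 1e-12:
        raise ValueError("delta_delta_G requires matching kT")
    return result_b.delta_g - result_a.delta_g


def bootstrap_deltaG(cvs, state_sequences: list[np.ndarray], basins: BasinDefinition,
                     msm_lag: float, frame_interval: float, kT: float = KT_300K,
                     B: int = 200, level: float = 0.95, seed: int = 0,
                     n_states: int | None = None) -> DeltaGResult:
    """Trajectory bootstrap of the basin free-energy difference.

    Trajectories are resampled with replacement B times; each replicate
    re-estimates the MSM (the tICA projection and clustering stay fixed
    from the full fit) and recomputes dG.  Replicates with an empty
    basin or a degenerate MSM are dropped and counted; more than 20%
    dropped is an error.  The CI is the percentile interval at
    ``level``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arrays = _cv_arrays(cvs)
    if len(arrays) < 2:
        raise ValueError("bootstrap needs at least two trajectories")
    if n_states is None:
        n_states = int(max(np.max(s) for s in state_sequences)) + 1

    msm = estimate_msm(state_sequences, msm_lag, frame_interval, n_states=n_states)
    points = np.concatenate(arrays, axis=0)
    weights = np.concatenate(stationary_frame_weights(msm, state_sequences))
    point_est = basin_deltaG_from_frames(points, weights, basins, kT, seed=seed)

    rng = np.random.default_rng(seed)
    n = len(arrays)
    reps = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            s_rep = [state_sequences[i] for i in idx]
            msm_rep = estimate_msm(s_rep, msm_lag, frame_interval, n_states=n_states)
            pts = np.concatenate([arrays[i] for i in idx], axis=0)
            w = np.concatenate(stationary_frame_weights(msm_rep, s_rep))
            reps.append(basin_deltaG_from_frames(pts, w, basins, kT).delta_g)
        except (ValueError, RuntimeError) as exc:
            dropped += 1
            logger.info("bootstrap replicate dropped: %s", exc)
    if dropped > 0.2 * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates dropped; the dataset is too sparse "
            "for these basins"
        )
    alpha = 1.0 - level
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return DeltaGResult(
        point_est.p_deep, point_est.p_shallow, point_est.delta_g, kT, basins,
        ci_lower=float(lo), ci_upper=float(hi), level=level,
        n_replicates=len(reps), n_dropped=dropped, seed=seed,
    )


def propose_basins(landscape: FreeEnergyLandscape) -> BasinDefinition:
    """Rectangles around the two lowest-F local minima, split mid-way.

    A helper for exploratory use: finds grid-local minima of F, keeps
    the two lowest, and splits the plane between them along the axis of
    larger (span-normalised) separation.  The basin at smaller depth is
    named deep.
    """
    f = landscape.free_energy
    valid = np.isfinite(f)
    n_d, n_t = f.shape
    minima = []
    for i in range(n_d):
        for j in range(n_t):
            if not valid[i, j]:
                continue
            neigh = f[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if f[i, j] <= np.nanmin(neigh):
                minima.append((f[i, j], i, j))
    minima.sort()
    if len(minima) < 2:
        raise ValueError("fewer than two local minima on the landscape")
    (_, i1, j1), (_, i2, j2) = minima[0], minima[1]
    dc, tc = landscape.d_centers, landscape.theta_centers
    c1 = np.array([dc[i1], tc[j1]])
    c2 = np.array([dc[i2], tc[j2]])
    span = np.array([dc[-1] - dc[0], tc[-1] - tc[0]])
    axis = int(np.argmax(np.abs(c2 - c1) / span))
    mid = 0.5 * (c1[axis] + c2[axis])
    lo = (landscape.d_edges[0], landscape.theta_edges[0])
    hi = (landscape.d_edges[-1], landscape.theta_edges[-1])

    def rect(center):
        if axis == 0:
            d_rng = (lo[0], mid) if center[0] < mid else (mid, hi[0])
            t_rng = (lo[1], hi[1])
        else:
            d_rng = (lo[0], hi[0])
            t_rng = (lo[1], mid) if center[1] < mid else (mid, hi[1])
        return (d_rng[0], d_rng[1], t_rng[0], t_rng[1])

    deep_c, shallow_c = (c1, c2) if c1[0] <= c2[0] else (c2, c1)
    return BasinDefinition(deep=rect(deep_c), shallow=rect(shallow_c))


def default_basins() -> BasinDefinition:
    """Deep/shallow split matching the default two-well study conditions."""
    return BasinDefinition(
        deep=(0.4, 1.475, -40.0, 90.0),
        shallow=(1.475, 2.8, -40.0, 90.0),
    )


def count_coordinating_waters(traj: Trajectory, topo: Topology,
                              target_atom_ids, d_max: float = 0.35) -> np.ndarray:
    """Per-frame count of water oxygens within ``d_max`` of any target atom.

    A distance-only coordination criterion (minimum image); each water
    is counted once even when it contacts several targets.
    """
    targets = np.asarray(target_atom_ids, dtype=int)
    if targets.size == 0:
        raise ValueError("target_atom_ids must not be empty")
    waters = topo.water_oxygens
    counts = np.zeros(traj.n_frames, dtype=int)
    if waters.size == 0:
        return counts
    box = np.asarray(traj.box)
    for f in range(traj.n_frames):
        tree = cKDTree(np.mod(traj.xyz[f, targets, :], box), boxsize=box)
        dist, _ = tree.query(np.mod(traj.xyz[f, waters, :], box), k=1,
                             distance_upper_bound=d_max)
        counts[f] = int(np.sum(np.isfinite(dist) & (dist <= d_max)))
    return counts
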