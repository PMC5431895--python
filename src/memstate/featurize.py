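"""Featurizers and the combined featurization scheme.

Seven featurizers describe the peptide-ligand-membrane system: three
for peptide conformation (backbone dihedrals, RMSD to a reference,
reciprocal interatomic distance distribution), two for local water
density (solvent-shell counts at 0.3 and 1.0 nm), and two for lipid
localization (a phosphorus solvent shell and an exponentially weighted
peptide-phosphorus distance).  Combining zero or one choice per group
— protein, water, lipid — and excluding the empty combination yields
35 distinct featurizations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .systems import Topology, Trajectory

logger = logging.getLogger(__name__)

PROTEIN_CHOICES = ("none", "dihedrals", "rmsd", "reciprocal_distances")
WATER_CHOICES = ("none", "shell_0.3nm", "shell_1.0nm")
LIPID_CHOICES = ("none", "lipid_shell", "lipid_weighted_distance")


@dataclass(frozen=True, order=True)
class FeatureSpec:
    """One combined featurization: 0 or 1 choice per subsystem."""

    protein: str = "none"
    water: str = "none"
    lipid: str = "none"

    def __post_init__(self) -> None:
        if self.protein not in PROTEIN_CHOICES:
            raise ValueError(f"unknown protein featurizer {self.protein!r}")
        if self.water not in WATER_CHOICES:
            raise ValueError(f"unknown water featurizer {self.water!r}")
        if self.lipid not in LIPID_CHOICES:
            raise ValueError(f"unknown lipid featurizer {self.lipid!r}")
        if (self.protein, self.water, self.lipid) == ("none", "none", "none"):
            raise ValueError("a featurization must select at least one subsystem")

    @property
    def label(self) -> str:
        return f"{self.protein}+{self.water}+{self.lipid}"

    @classmethod
    def from_label(cls, label: str) -> "FeatureSpec":
        p, w, l = label.split("+")
        return cls(p, w, l)


@dataclass
class FeatureMatrix:
    """Per-trajectory feature table: ``(n_frames, n_features)``."""

    values: np.ndarray
    labels: list[str]
    frame_interval: float  # ns
    spec: FeatureSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (frames x features)")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("one label per feature column is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            h.create_dataset("values", data=self.values)
            h.create_dataset("labels", data=np.array(self.labels, dtype="S"))
            h.attrs["frame_interval"] = self.frame_interval
            h.attrs["spec"] = self.spec.label if self.spec else ""

    @classmethod
    def load_hdf5(cls, path) -> "FeatureMatrix":
        import h5py

        with h5py.File(path, "r") as h:
            values = h["values"][:]
            labels = [s.decode() for s in h["labels"][:]]
            fi = float(h.attrs["frame_interval"])
            spec_label = h.attrs.get("spec", "")
            spec = FeatureSpec.from_label(spec_label) if spec_label else None
        return cls(values, labels, fi, spec)


def enumerate_combined_featurizations() -> list[FeatureSpec]:
    """All 35 combined featurizations in deterministic order."""
    specs = []
    for p, w, l in itertools.product(PROTEIN_CHOICES, WATER_CHOICES, LIPID_CHOICES):
        if (p, w, l) == ("none", "none", "none"):
            continue
        specs.append(FeatureSpec(p, w, l))
    return specs


# ---------------------------------------------------------------------------
# Protein featurizers
# ---------------------------------------------------------------------------


def _dihedral_angles(p0, p1, p2, p3):
    """Signed dihedrals (IUPAC convention) for stacked point arrays."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.arctan2(y, x)


def backbone_dihedrals(traj: Trajectory, topo: Topology) -> FeatureMatrix:
    """phi/psi backbone dihedrals encoded as (sin, cos) pairs.

    Dihedrals spanning a chain break (non-consecutive residue numbers)
    are omitted and logged.
    """
    residues: dict[int, dict[str, int]] = {}
    for i in topo.indices("backbone", "alpha_carbon"):
        if topo.names[i] in ("N", "CA", "C"):
            residues.setdefault(int(topo.residue_numbers[i]), {})[topo.names[i]] = i
    nums = sorted(r for r, atoms in residues.items() if set(atoms) >= {"N", "CA", "C"})
    quads: list[tuple[str, tuple[int, int, int, int]]] = []
    for prev, cur in zip(nums[:-1], nums[1:]):
        if cur != prev + 1:
            logger.info("chain break between residues %d and %d; dihedrals omitted", prev, cur)
            continue
        a, bres = residues[prev], residues[cur]
        quads.append((f"phi_{cur}", (a["C"], bres["N"], bres["CA"], bres["C"])))
        quads.append((f"psi_{prev}", (a["N"], a["CA"], a["C"], bres["N"])))
    if not quads:
        raise ValueError("no backbone dihedrals could be constructed")
    idx = np.array([q[1] for q in quads])
    xyz = traj.xyz
    ang = _dihedral_angles(
        xyz[:, idx[:, 0]], xyz[:, idx[:, 1]], xyz[:, idx[:, 2]], xyz[:, idx[:, 3]]
    )
    values = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    labels = [f"{q[0]}_sin" for q in quads] + [f"{q[0]}_cos" for q in quads]
    return FeatureMatrix(values, labels, traj.frame_interval)


def rmsd_to_reference(traj: Trajectory, topo: Topology, reference_xyz: np.ndarray) -> FeatureMatrix:
    """Optimal-superposition RMSD of the peptide heavy atoms (nm).

    Rotation and translation are minimised per frame (Kabsch); the
    reference is a full-system frame with the same atom ordering.
    """
    idx = topo.protein_heavy
    if idx.size < 3:
        raise ValueError("RMSD featurizer needs at least 3 protein heavy atoms")
    ref = np.asarray(reference_xyz, dtype=float)[idx]
    ref = ref - ref.mean(axis=0)
    x = traj.xyz[:, idx, :]
    x = x - x.mean(axis=1, keepdims=True)
    # Kabsch per frame: apply the optimal rotation and measure the residual
    # (the explicit residual avoids cancellation error near zero RMSD)
    b = np.einsum("fna,nb->fab", x, ref)  # x^T ref per frame
    u, _, vt = np.linalg.svd(b)
    det = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    u[:, :, -1] *= det[:, None]
    rot = u @ vt
    res = x @ rot - ref
    values = np.sqrt(np.einsum("fna,fna->f", res, res) / idx.size)[:, None]
    return FeatureMatrix(values, ["rmsd_nm"], traj.frame_interval)


DEFAULT_RECIP_BIN_EDGES = np.linspace(0.0, 10.0, 51)  # nm^-1


def reciprocal_distance_histogram(traj: Trajectory, topo: Topology,
                                  bin_edges: np.ndarray | None = None) -> FeatureMatrix:
    """Normalised histogram of reciprocal heavy-atom pair distances.

    All unordered pairs among peptide plus ligand heavy atoms enter; each
    row is normalised to unit mass.
    """
    if bin_edges is None:
        bin_edges = DEFAULT_RECIP_BIN_EDGES
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = topo.heavy
    if idx.size < 2:
        raise ValueError("need at least two heavy atoms for pair distances")
    ii, jj = np.triu_indices(idx.size, k=1)
    values = np.empty((traj.n_frames, bin_edges.size - 1))
    x = traj.xyz[:, idx, :]
    chunk = max(1, int(2e7 // max(ii.size, 1)))
    for f0 in range(0, traj.n_frames, chunk):
        seg = x[f0:f0 + chunk]
        d = np.linalg.norm(seg[:, ii] - seg[:, jj], axis=-1)
        if np.any(d < 1e-6):
            raise ValueError("coincident heavy atoms (d < 1e-6 nm) in trajectory")
        r = 1.0 / d
        for k in range(seg.shape[0]):
            h, _ = np.histogram(r[k], bins=bin_edges)
            tot = h.sum()
            values[f0 + k] = h / tot if tot else h
    labels = [f"recip_{lo:.2f}_{hi:.2f}" for lo, hi in zip(bin_edges[:-1], bin_edges[1:])]
    return FeatureMatrix(values, labels, traj.frame_interval)


# ---------------------------------------------------------------------------
# Solvent / lipid featurizers
# ---------------------------------------------------------------------------


def solvent_shell_counts(traj: Trajectory, topo: Topology, solvent_role: str,
                         radius_nm: float) -> FeatureMatrix:
    """Per heavy atom, count of solvent atoms within ``radius_nm``.

    Minimum-image convention on the orthorhombic box; implemented with a
    periodic KD-tree per frame.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if solvent_role not in ("water_oxygen", "lipid_phosphorus"):
        raise ValueError("solvent_role must be water_oxygen or lipid_phosphorus")
    if radius_nm > min(traj.box) / 2:
        raise ValueError("radius exceeds half the smallest box length; "
                         "minimum image is invalid")
    heavy = topo.heavy
    solvent = topo.indices(solvent_role)
    values = np.zeros((traj.n_frames, heavy.size))
    if solvent.size:
        box = np.asarray(traj.box)
        for f in range(traj.n_frames):
            pts = np.mod(traj.xyz[f, solvent, :], box)
            tree = cKDTree(pts, boxsize=box)
            q = np.mod(traj.xyz[f, heavy, :], box)
            values[f] = tree.query_ball_point(q, radius_nm, return_length=True)
    tag = "wat" if solvent_role == "water_oxygen" else "lip"
    labels = [f"shell_{tag}_{radius_nm:g}_{topo.names[i]}{topo.residue_numbers[i]}_{i}"
              for i in heavy]
    return FeatureMatrix(values, labels, traj.frame_interval)


def lipid_weighted_distance(traj: Trajectory, topo: Topology,
                            sigma_nm: float = 0.3) -> FeatureMatrix:
    """Smooth lipid proximity: ``sum_j exp(-d_ij / sigma)`` per protein heavy atom.

    Distances use the minimum image; the sum runs over all lipid
    phosphorus atoms, giving a bounded, monotone proximity weight.
    """
    prot = topo.protein_heavy
    lip = topo.lipid_phosphorus
    if lip.size < 1:
        raise ValueError("lipid_weighted_distance requires at least one phosphorus")
    box = np.asarray(traj.box)
    values = np.empty((traj.n_frames, prot.size))
    chunk = max(1, int(2e7 // max(prot.size * lip.size, 1)))
    for f0 in range(0, traj.n_frames, chunk):
        seg = traj.xyz[f0:f0 + chunk]
        delta = seg[:, prot, None, :] - seg[:, None, lip, :]
        delta -= box * np.round(delta / box)
        d = np.linalg.norm(delta, axis=-1)
        values[f0:f0 + chunk] = np.exp(-d / sigma_nm).sum(axis=-1)
    labels = [f"lipw_{topo.names[i]}{topo.residue_numbers[i]}_{i}" for i in prot]
    return FeatureMatrix(values, labels, traj.frame_interval)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureParams:
    """Shared parameters for :func:`assemble_features`."""

    reference_xyz: np.ndarray | None = None  # for the RMSD featurizer
    recip_bin_edges: np.ndarray | None = None
    lipid_sigma_nm: float = 0.3
    lipid_shell_radius_nm: float = 1.0

    _WATER_RADII = {"shell_0.3nm": 0.3, "shell_1.0nm": 1.0}


def assemble_features(traj: Trajectory, topo: Topology, spec: FeatureSpec,
                      params: FeatureParams | None = None) -> FeatureMatrix:
    """Column-concatenate the featurizers selected by ``spec``."""
    params = params or FeatureParams()
    parts: list[FeatureMatrix] = []
    if spec.protein == "dihedrals":
        parts.append(backbone_dihedrals(traj, topo))
    elif spec.protein == "rmsd":
        ref = params.reference_xyz if params.reference_xyz is not None else traj.xyz[0]
        parts.append(rmsd_to_reference(traj, topo, ref))
    elif spec.protein == "reciprocal_distances":
        parts.append(reciprocal_distance_histogram(traj, topo, params.recip_bin_edges))
    if spec.water != "none":
        radius = FeatureParams._WATER_RADII[spec.water]
        parts.append(solvent_shell_counts(traj, topo, "water_oxygen", radius))
    if spec.lipid == "lipid_shell":
        parts.append(
            solvent_shell_counts(traj, topo, "lipid_phosphorus", params.lipid_shell_radius_nm)
        )
    elif spec.lipid == "lipid_weighted_distance":
        parts.append(lipid_weighted_distance(traj, topo, params.lipid_sigma_nm))
    values = np.concatenate([p.values for p in parts], axis=1)
    labels = [lab for p in parts for lab in p.labels]
    return FeatureMatrix(values, labels, traj.frame_interval, spec)
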