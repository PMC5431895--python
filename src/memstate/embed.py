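"""Embed (depth, angle) trajectories as toy atomistic systems.

Each (d, theta) frame is realised as a rigid-body placement of a
pseudo-peptide template in a slab geometry: lipid phosphorus markers on
jittered lattices at the two leaflet planes, and water oxygens sampled
from a z-graded density that is bulk-like above the headgroup region,
decays linearly through it, and vanishes in the hydrocarbon core.  The
construction guarantees that the depth/angle collective variables
recomputed from the atoms reproduce the generating values exactly, so
the whole downstream pipeline can be validated round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .systems import Topology, Trajectory
from .synthetic import CVTrajectorySet

#: peptide residues whose alpha carbons define the binding-site centroid
BINDING_RESIDUES = (9, 12, 21, 25)
#: residues (plus the zinc) whose centroid defines the distal end of the body axis
DISTAL_RESIDUES = (3, 35, 48)
#: residues coordinating the structural zinc
ZINC_RESIDUES = (1, 31, 34, 50)

_RESIDUE_NAMES = {
    1: "HIS", 3: "PHE", 9: "MET", 12: "THR", 21: "LEU", 25: "VAL",
    31: "CYS", 34: "CYS", 35: "GLY", 48: "ASN", 50: "CYS",
}


@dataclass
class PeptideTemplate:
    """Labelled pseudo-atom coordinates of the peptide in a body frame."""

    topology: Topology
    xyz: np.ndarray  # (n_atoms, 3) nm

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.topology.n_atoms, 3):
            raise ValueError("template coordinates must match its topology")

    def binding_centroid(self) -> np.ndarray:
        idx = [self.topology.alpha_carbon(r) for r in BINDING_RESIDUES]
        return self.xyz[idx].mean(axis=0)

    def distal_centroid(self) -> np.ndarray:
        idx = [self.topology.alpha_carbon(r) for r in DISTAL_RESIDUES]
        pts = [self.xyz[i] for i in idx]
        zn = self.topology.zinc
        if zn.size != 1:
            raise ValueError("template must contain exactly one zinc")
        pts.append(self.xyz[zn[0]])
        return np.mean(pts, axis=0)


def default_template(n_residues: int = 50) -> PeptideTemplate:
    """A compact helical pseudo-peptide (~2.7 nm) with the canonical residues.

    Backbone N/CA/C per residue plus a CB side-chain marker (except the
    glycine), one zinc near the centroid of its coordinating cysteines/
    histidine, and an eight-atom ligand ring near the binding site.
    """
    radius, rise, turn = 0.45, 0.055, np.deg2rad(100.0)
    i = np.arange(1, n_residues + 1)
    ca = np.stack(
        [radius * np.cos(turn * i), radius * np.sin(turn * i), rise * i], axis=1
    )
    # chain tangents for backbone placement (central differences, clamped ends)
    tang = np.gradient(ca, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    radial = ca.copy()
    radial[:, 2] = 0.0
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)

    names: list[str] = []
    resnames: list[str] = []
    resnums: list[int] = []
    roles: list[str] = []
    coords: list[np.ndarray] = []
    for k in range(n_residues):
        num = k + 1
        rname = _RESIDUE_NAMES.get(num, "ALA")
        entries = [
            ("N", "backbone", ca[k] - 0.145 * tang[k] + 0.05 * radial[k]),
            ("CA", "alpha_carbon", ca[k]),
            ("C", "backbone", ca[k] + 0.145 * tang[k] + 0.05 * radial[k]),
        ]
        if rname != "GLY":
            entries.append(("CB", "protein_heavy", ca[k] + 0.15 * radial[k]))
        for name, role, xyz in entries:
            names.append(name)
            resnames.append(rname)
            resnums.append(num)
            roles.append(role)
            coords.append(xyz)

    zn_site = np.mean([ca[r - 1] for r in ZINC_RESIDUES], axis=0)
    zn_dir = zn_site - np.array([0.0, 0.0, zn_site[2]])
    nrm = np.linalg.norm(zn_dir)
    zn_pos = zn_site + (0.2 * zn_dir / nrm if nrm > 1e-9 else np.array([0.2, 0.0, 0.0]))
    names.append("ZN")
    resnames.append("ZN")
    resnums.append(n_residues + 1)
    roles.append("zinc")
    coords.append(zn_pos)

    b = np.mean([ca[r - 1] for r in BINDING_RESIDUES], axis=0)
    out = b - np.array([0.0, 0.0, b[2]])
    out = out / np.linalg.norm(out)
    lig_center = b + 0.35 * out
    ring_u = np.cross(out, [0.0, 0.0, 1.0])
    ring_u /= np.linalg.norm(ring_u)
    for j in range(8):
        ang = 2 * np.pi * j / 8
        pos = lig_center + 0.25 * (np.cos(ang) * ring_u + np.sin(ang) * np.array([0, 0, 1.0]))
        names.append(f"C{j + 1}")
        resnames.append("LIG")
        resnums.append(n_residues + 2)
        roles.append("ligand_heavy")
        coords.append(pos)

    topo = Topology(names, resnames, np.array(resnums), np.array(roles, dtype=object))
    return PeptideTemplate(topo, np.array(coords))


@dataclass
class EmbedConfig:
    """Geometry of the toy membrane/solvent system.

    Phosphorus planes sit at ``membrane center +/- leaflet_z``; water
    density is ``water_bulk_density`` above the planes, decays linearly
    through the headgroup region and is zero inside
    ``hydrocarbon_halfwidth`` of the center.  Per-leaflet z jitter is
    re-centred every frame so the leaflet pseudo-planes stay exact.
    """

    leaflet_z: float = 2.0  # nm
    hydrocarbon_halfwidth: float = 1.2  # nm
    water_bulk_density: float = 4.0  # count / nm^3 (thinned bulk water)
    n_lipids_per_leaflet: int = 64
    box: tuple[float, float, float] = (6.0, 6.0, 12.0)
    seed: int = 0
    lipid_xy_jitter: float = 0.08  # nm
    lipid_z_jitter: float = 0.05  # nm
    #: thermal jitter of peptide atoms (nm); the CV-defining atoms (the named
    #: alpha carbons and the zinc) are never jittered so depth/angle stay exact
    peptide_jitter: float = 0.01
    peptide_template: PeptideTemplate = field(default_factory=default_template)

    def __post_init__(self) -> None:
        if not self.hydrocarbon_halfwidth < self.leaflet_z:
            raise ValueError("hydrocarbon_halfwidth must be < leaflet_z")
        if self.leaflet_z >= self.box[2] / 2:
            raise ValueError("leaflet planes must fit inside the box")
        topo = self.peptide_template.topology
        for role in ("alpha_carbon", "backbone", "protein_heavy", "ligand_heavy", "zinc"):
            if topo.indices(role).size == 0:
                raise ValueError(f"peptide template lacks atoms with role {role!r}")


def _rotation_to_x(u: np.ndarray) -> np.ndarray:
    """Orthonormal matrix R with R @ u = x-hat (deterministic choice)."""
    e1 = u / np.linalg.norm(u)
    a = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, a)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=0)


def _water_sampler(cfg: EmbedConfig):
    """Inverse-CDF sampler for the water z coordinate (box frame)."""
    bz = cfg.box[2]
    z0 = bz / 2.0
    z = np.linspace(0.0, bz, 4001)
    a = np.abs(z - z0)
    h, L = cfg.hydrocarbon_halfwidth, cfg.leaflet_z
    rho = np.where(a >= L, 1.0, np.where(a < h, 0.0, (a - h) / (L - h)))
    rho = rho * cfg.water_bulk_density
    cdf = np.concatenate([[0.0], np.cumsum((rho[1:] + rho[:-1]) / 2 * np.diff(z))])
    total = cdf[-1] * cfg.box[0] * cfg.box[1]  # expected count
    n_waters = int(round(total))
    cdf_n = cdf / cdf[-1]

    def sample(rng: np.random.Generator) -> np.ndarray:
        zz = np.interp(rng.random(n_waters), cdf_n, z)
        xy = rng.random((n_waters, 2)) * np.array(cfg.box[:2])
        return np.column_stack([xy, zz])

    return n_waters, sample


def _lipid_lattice(cfg: EmbedConfig) -> np.ndarray:
    n = cfg.n_lipids_per_leaflet
    m = int(np.ceil(np.sqrt(n)))
    gx = (np.arange(m) + 0.5) * cfg.box[0] / m
    gy = (np.arange(m) + 0.5) * cfg.box[1] / m
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    return np.column_stack([xx.ravel()[:n], yy.ravel()[:n]])


def build_topology(cfg: EmbedConfig) -> Topology:
    """Full-system topology: peptide+zinc+ligand, lipids, then waters."""
    pep = cfg.peptide_template.topology
    n_waters, _ = _water_sampler(cfg)
    names = list(pep.names)
    resnames = list(pep.residue_names)
    resnums = list(pep.residue_numbers)
    roles = list(pep.roles)
    base = int(np.max(pep.residue_numbers)) + 1
    for j in range(2 * cfg.n_lipids_per_leaflet):
        names.append("P")
        resnames.append("LIP")
        resnums.append(base + j)
        roles.append("lipid_phosphorus")
    base += 2 * cfg.n_lipids_per_leaflet
    for j in range(n_waters):
        names.append("O")
        resnames.append("HOH")
        resnums.append(base + j)
        roles.append("water_oxygen")
    return Topology(names, resnames, np.array(resnums), np.array(roles, dtype=object))


def embed_frames(cvs: CVTrajectorySet, cfg: EmbedConfig) -> tuple[Topology, list[Trajectory]]:
    """Realise every (d, theta) frame as an atomistic configuration.

    Returns the shared topology and one :class:`Trajectory` per input
    trajectory.  The peptide is placed with its binding-site centroid at
    depth ``d`` above the membrane center and its body axis tilted by
    ``theta`` out of the membrane plane (random azimuth); recomputing
    the collective variables from the output reproduces the inputs to
    machine precision.
    """
    template = cfg.peptide_template
    topo = build_topology(cfg)
    n_waters, sample_waters = _water_sampler(cfg)
    lattice = _lipid_lattice(cfg)
    rng = np.random.default_rng(cfg.seed)

    b = template.binding_centroid()
    q = template.distal_centroid()
    body = (template.xyz - b) @ _rotation_to_x(q - b).T  # axis along +x, centroid at 0

    # atoms that define the collective variables stay rigid under jitter
    cv_atoms = np.zeros(template.topology.n_atoms, dtype=bool)
    for r in BINDING_RESIDUES + DISTAL_RESIDUES:
        cv_atoms[template.topology.alpha_carbon(r)] = True
    cv_atoms[template.topology.zinc] = True

    bx, by, bz = cfg.box
    z0 = bz / 2.0
    center_xy = np.array([bx / 2.0, by / 2.0])
    margin = 0.1
    n_pep = template.topology.n_atoms
    n_lip = 2 * cfg.n_lipids_per_leaflet

    out: list[Trajectory] = []
    for cv in cvs.trajectories:
        xyz = np.empty((len(cv), topo.n_atoms, 3))
        for f, (d, theta) in enumerate(cv):
            th = np.deg2rad(theta)
            az = rng.random() * 2 * np.pi
            # tilt about y so the body axis x-hat gains a +sin(theta) z component
            ry = np.array(
                [[np.cos(th), 0.0, -np.sin(th)],
                 [0.0, 1.0, 0.0],
                 [np.sin(th), 0.0, np.cos(th)]]
            )
            rz = np.array(
                [[np.cos(az), -np.sin(az), 0.0],
                 [np.sin(az), np.cos(az), 0.0],
                 [0.0, 0.0, 1.0]]
            )
            pep = body @ (rz @ ry).T
            pep += np.array([center_xy[0], center_xy[1], z0 + d])
            if cfg.peptide_jitter > 0:
                wig = rng.standard_normal(pep.shape) * cfg.peptide_jitter
                wig[cv_atoms] = 0.0
                pep = pep + wig
            if (pep.min() < margin or np.any(pep.max(axis=0) > np.array(cfg.box) - margin)):
                raise ValueError(
                    f"peptide at (d={d:.3g} nm, theta={theta:.3g} deg) collides with "
                    "the box boundary; increase the box dimensions"
                )
            xyz[f, :n_pep] = pep

            lipids = np.empty((n_lip, 3))
            for s, sign in enumerate((1.0, -1.0)):
                sl = slice(s * cfg.n_lipids_per_leaflet, (s + 1) * cfg.n_lipids_per_leaflet)
                xy = lattice + rng.standard_normal(lattice.shape) * cfg.lipid_xy_jitter
                xy[:, 0] %= bx
                xy[:, 1] %= by
                dz = rng.standard_normal(cfg.n_lipids_per_leaflet) * cfg.lipid_z_jitter
                dz -= dz.mean()  # keep the leaflet pseudo-plane exact
                lipids[sl, :2] = xy
                lipids[sl, 2] = z0 + sign * cfg.leaflet_z + dz
            xyz[f, n_pep:n_pep + n_lip] = lipids
            xyz[f, n_pep + n_lip:] = sample_waters(rng)

        out.append(Trajectory(xyz, frame_interval=cvs.frame_interval, box=np.array(cfg.box)))
    return topo, out
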