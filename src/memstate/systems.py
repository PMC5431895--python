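"""Shared containers for molecular systems.

A :class:`Topology` labels every atom with a *role* describing how the
analysis treats it (peptide heavy atom, backbone atom, alpha carbon,
ligand heavy atom, water oxygen, lipid phosphorus pseudo-atom, or
structural zinc).  Roles are mutually exclusive; helper selectors
combine them where a featurizer wants a union (e.g. "all protein heavy
atoms" includes backbone and alpha-carbon atoms).

Coordinates are stored in nanometres in orthorhombic boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLES = (
    "protein_heavy",
    "backbone",
    "alpha_carbon",
    "ligand_heavy",
    "water_oxygen",
    "lipid_phosphorus",
    "zinc",
)

#: roles that together make up the peptide's heavy atoms
PROTEIN_ROLES = ("protein_heavy", "backbone", "alpha_carbon")


@dataclass
class Topology:
    """Atom metadata for one system.

    Parameters
    ----------
    names : list of str
        PDB-style atom names (``CA``, ``N``, ``P``, ``O`` ...).
    residue_names : list of str
        Three-letter residue names (``MET``, ``HOH``, ``LIP`` ...).
    residue_numbers : array of int
        Residue sequence numbers; the peptide uses its canonical
        numbering (M9, T12, L21, V25, F3, G35, N48, H1, C31, C34, C50).
    roles : array of str
        One role per atom, drawn from :data:`ROLES`.
    """

    names: list[str]
    residue_names: list[str]
    residue_numbers: np.ndarray
    roles: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        n = len(self.names)
        if not (len(self.residue_names) == self.residue_numbers.size == self.roles.size == n):
            raise ValueError("topology fields must all have one entry per atom")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown atom roles: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def indices(self, *roles: str) -> np.ndarray:
        """Indices of atoms whose role is in ``roles`` (original order)."""
        mask = np.isin(self.roles, roles)
        return np.nonzero(mask)[0]

    @property
    def protein_heavy(self) -> np.ndarray:
        """All peptide heavy atoms (side chain + backbone + CA)."""
        return self.indices(*PROTEIN_ROLES)

    @property
    def heavy(self) -> np.ndarray:
        """Peptide plus ligand heavy atoms (the featurizers' targets)."""
        return self.indices(*PROTEIN_ROLES, "ligand_heavy")

    @property
    def water_oxygens(self) -> np.ndarray:
        return self.indices("water_oxygen")

    @property
    def lipid_phosphorus(self) -> np.ndarray:
        return self.indices("lipid_phosphorus")

    @property
    def zinc(self) -> np.ndarray:
        return self.indices("zinc")

    def alpha_carbon(self, residue_number: int) -> int:
        """Index of the CA atom of one peptide residue."""
        ca = self.indices("alpha_carbon")
        hits = ca[self.residue_numbers[ca] == residue_number]
        if hits.size != 1:
            raise KeyError(
                f"expected exactly one alpha carbon for residue {residue_number}, "
                f"found {hits.size}"
            )
        return int(hits[0])


@dataclass
class Trajectory:
    """Coordinates for one trajectory: ``(n_frames, n_atoms, 3)`` in nm."""

    xyz: np.ndarray
    frame_interval: float  # ns
    box: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0, 10.0]))

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ns)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive orthorhombic lengths (nm)")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]


# ---------------------------------------------------------------------------
# mdtraj interchange: PDB topologies, XTC/DCD coordinate sets
# ---------------------------------------------------------------------------

_ELEMENT_BY_NAME = {"N": "N", "CA": "C", "C": "C", "CB": "C", "O": "O", "P": "P", "ZN": "Zn"}

# residue names that encode non-peptide roles in written PDB files
_WATER_RES = "HOH"
_LIPID_RES = "LIP"
_LIGAND_RES = "LIG"
_ZINC_RES = "ZN"


def to_mdtraj(topology: Topology, trajectory: Trajectory):
    """Convert to an :class:`mdtraj.Trajectory` (for PDB/XTC/DCD output)."""
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    chain = top.add_chain()
    current = None
    residue = None
    for i in range(topology.n_atoms):
        key = (topology.residue_names[i], int(topology.residue_numbers[i]))
        if key != current:
            residue = top.add_residue(topology.residue_names[i], chain,
                                      resSeq=int(topology.residue_numbers[i]))
            current = key
        name = topology.names[i]
        symbol = _ELEMENT_BY_NAME.get(name, name[0])
        try:
            e = elem.get_by_symbol(symbol)
        except KeyError:
            e = elem.virtual
        top.add_atom(name, e, residue)
    n_frames = trajectory.n_frames
    unitcell = np.tile(trajectory.box, (n_frames, 1))
    angles = np.full((n_frames, 3), 90.0)
    return md.Trajectory(
        trajectory.xyz.copy(),
        top,
        unitcell_lengths=unitcell,
        unitcell_angles=angles,
    )


def _role_for_atom(residue_name: str, atom_name: str) -> str | None:
    if residue_name == _WATER_RES:
        return "water_oxygen" if atom_name.startswith("O") else None
    if residue_name == _LIPID_RES:
        return "lipid_phosphorus" if atom_name.startswith("P") else None
    if residue_name == _ZINC_RES or atom_name == "ZN":
        return "zinc"
    if residue_name == _LIGAND_RES:
        return None if atom_name.startswith("H") else "ligand_heavy"
    # peptide atom
    if atom_name.startswith("H"):
        return None
    if atom_name == "CA":
        return "alpha_carbon"
    if atom_name in ("N", "C", "O"):
        return "backbone" if atom_name != "O" else "protein_heavy"
    return "protein_heavy"


def from_mdtraj(mdt) -> tuple[Topology, Trajectory]:
    """Convert an mdtraj trajectory, inferring atom roles from names.

    Atoms without a recognised role (e.g. hydrogens) are dropped.
    """
    names, resnames, resnums, roles, keep = [], [], [], [], []
    for atom in mdt.topology.atoms:
        role = _role_for_atom(atom.residue.name, atom.name)
        if role is None:
            continue
        keep.append(atom.index)
        names.append(atom.name)
        resnames.append(atom.residue.name)
        resnums.append(atom.residue.resSeq)
        roles.append(role)
    topo = Topology(names, resnames, np.array(resnums), np.array(roles, dtype=object))
    if mdt.unitcell_lengths is not None:
        box = np.asarray(mdt.unitcell_lengths[0], dtype=float)
    else:
        span = mdt.xyz.max(axis=(0, 1)) - mdt.xyz.min(axis=(0, 1))
        box = span + 1.0
    dt = mdt.timestep / 1000.0 if mdt.n_frames > 1 else 1.0  # mdtraj time is ps
    traj = Trajectory(np.asarray(mdt.xyz[:, keep, :], dtype=float), frame_interval=dt, box=box)
    return topo, traj


def save_pdb(path, topology: Topology, trajectory: Trajectory) -> None:
    to_mdtraj(topology, trajectory)[0].save_pdb(str(path))


def save_xtc(path, topology: Topology, trajectory: Trajectory) -> None:
    to_mdtraj(topology, trajectory).save_xtc(str(path))


def save_dcd(path, topology: Topology, trajectory: Trajectory) -> None:
    to_mdtraj(topology, trajectory).save_dcd(str(path))


def load_system(topology_path, trajectory_path=None, frame_interval: float | None = None):
    """Read a PDB/GRO topology and optionally an XTC/DCD trajectory.

    Returns ``(Topology, Trajectory)``; roles are inferred from residue
    and atom names (``HOH`` oxygens, ``LIP`` phosphorus markers, ``LIG``
    heavy atoms, ``ZN``, peptide backbone/CA/side-chain atoms).
    """
    import mdtraj as md

    if trajectory_path is None:
        mdt = md.load(str(topology_path))
    else:
        mdt = md.load(str(trajectory_path), top=str(topology_path))
    topo, traj = from_mdtraj(mdt)
    if frame_interval is not None:
        traj.frame_interval = float(frame_interval)
    return topo, traj
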