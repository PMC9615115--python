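"""Core in-memory containers: topology, frames, subsets, periodic geometry.

All positions are in Angstrom, charges in elementary charge units, times
in picoseconds.  The box is stored as three lattice vectors (rows of a
3x3 matrix); orthorhombic boxes are simply diagonal.  Geometry helpers
use the minimum-image convention throughout, so coordinates never need
to be wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: water-site roles
ROLE_O = "O"
ROLE_H1 = "H1"
ROLE_H2 = "H2"
ROLE_VIRTUAL = "virtual"
ROLE_NA = "n/a"

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class TopologyError(ValueError):
    """Raised for inconsistent or incomplete topologies."""


@dataclass
class Topology:
    """Static description of the atoms of a system.

    Parameters are parallel per-atom arrays.  ``molecule_id`` groups atoms
    into molecules (each water molecule is one id); ``water_site_role``
    labels the sites of 3/4-site water models ('O', 'H1', 'H2', 'virtual',
    or 'n/a' for non-water atoms).
    """

    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_index: np.ndarray
    element: np.ndarray
    partial_charge: np.ndarray
    molecule_id: np.ndarray
    is_water: np.ndarray
    water_site_role: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        for attr in ("residue_name", "residue_index", "element",
                     "partial_charge", "molecule_id", "is_water",
                     "water_site_role"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"field {attr!r} length mismatch")
        self.partial_charge = np.asarray(self.partial_charge, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.is_water = np.asarray(self.is_water, dtype=bool)
        self._validate_waters()

    # -- derived lookups ------------------------------------------------
    def _validate_waters(self) -> None:
        for mol in self.water_molecule_ids():
            roles = self.water_site_role[self.molecule_id == mol]
            n_o = int(np.sum(roles == ROLE_O))
            n_h = int(np.sum((roles == ROLE_H1) | (roles == ROLE_H2)))
            if n_o != 1 or n_h != 2:
                raise TopologyError(
                    f"water molecule {mol} must have exactly one O and two H "
                    f"sites (found {n_o} O, {n_h} H)")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def water_molecule_ids(self) -> np.ndarray:
        return np.unique(self.molecule_id[self.is_water])

    def atoms_of_molecule(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_id == mol_id)

    def water_sites(self, mol_id: int) -> dict[str, int]:
        """Atom indices of the O/H1/H2 (and virtual, if any) sites."""
        idx = self.atoms_of_molecule(mol_id)
        out: dict[str, int] = {}
        for i in idx:
            role = self.water_site_role[i]
            if role != ROLE_NA:
                out[str(role)] = int(i)
        return out

    def molecule_charge(self, mol_id: int) -> float:
        return float(np.sum(self.partial_charge[self.atoms_of_molecule(mol_id)]))

    def charged_site_mask(self) -> np.ndarray:
        return self.partial_charge != 0.0

    def solute_atom_indices(self, exclude_ions: bool = True) -> np.ndarray:
        """Non-water atoms; monatomic ions excluded from the solute by default."""
        mask = ~self.is_water
        if exclude_ions:
            ion_names = {"NA", "CL", "K", "MG", "CA2", "NA+", "CL-"}
            ions = np.array([str(r).strip().upper() in ion_names
                             for r in self.residue_name])
            mask &= ~ions
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """One configuration: positions (n_atoms, 3) plus periodic box."""

    positions: np.ndarray
    box_vectors: np.ndarray
    vacuum_axis: str = "z"
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box_vectors = np.asarray(self.box_vectors, dtype=float)
        if self.box_vectors.shape != (3, 3):
            raise ValueError("box_vectors must be a 3x3 matrix of lattice vectors")
        if abs(np.linalg.det(self.box_vectors)) < 1e-12:
            raise ValueError("degenerate box: lattice vectors span zero volume")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.vacuum_axis not in AXIS_INDEX:
            raise ValueError(f"vacuum_axis must be x/y/z, got {self.vacuum_axis!r}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.box_vectors.copy(),
                     self.vacuum_axis, self.time)


@dataclass
class Subset:
    """A named per-frame selection of water molecule ids."""

    name: str
    members_per_frame: list[set[int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.members_per_frame)

    def mean_size(self) -> float:
        if not self.members_per_frame:
            return 0.0
        return float(np.mean([len(m) for m in self.members_per_frame]))

    @classmethod
    def constant(cls, name: str, members: Iterable[int], n_frames: int) -> "Subset":
        mem = set(int(m) for m in members)
        return cls(name, [set(mem) for _ in range(n_frames)])


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

_NEIGHBOR_SHIFTS = np.array([[i, j, k]
                             for i in (-1, 0, 1)
                             for j in (-1, 0, 1)
                             for k in (-1, 0, 1)], dtype=float)


def minimum_image_displacements(dx: np.ndarray, box_vectors: np.ndarray) -> np.ndarray:
    """Map raw displacement vectors to their minimum images.

    Fractional-coordinate rounding is exact for orthorhombic cells; for
    triclinic cells it is refined by a search over the 27 neighboring
    images (rounding alone can pick a non-minimal image in skewed cells).
    ``dx`` has shape (..., 3).
    """
    box = np.asarray(box_vectors, dtype=float)
    if abs(np.linalg.det(box)) < 1e-12:
        raise ValueError("degenerate box")
    frac = np.asarray(dx, dtype=float) @ np.linalg.inv(box)
    frac -= np.round(frac)
    d0 = frac @ box
    if np.allclose(box, np.diag(np.diag(box))):
        return d0
    cand = d0[..., None, :] + (_NEIGHBOR_SHIFTS @ box)      # (..., 27, 3)
    norms = np.einsum("...ki,...ki->...k", cand, cand)
    best = np.argmin(norms, axis=-1)
    return np.take_along_axis(cand, best[..., None, None], axis=-2)[..., 0, :]


def minimum_image_vector(frame: Frame, a: int, b: int) -> np.ndarray:
    """Shortest periodic displacement from atom ``a`` to atom ``b`` (Angstrom)."""
    dx = frame.positions[b] - frame.positions[a]
    return minimum_image_displacements(dx, frame.box_vectors)


def minimum_image_distance(frame: Frame, a: int, b: int) -> float:
    return float(np.linalg.norm(minimum_image_vector(frame, a, b)))


def reflect_frame(frame: Frame, plane: str = "yz", about: float = 0.0) -> Frame:
    """Reflect all coordinates through a plane perpendicular to one axis.

    ``plane='yz'`` negates x (mirror through the yz plane at x=about);
    ``plane='xz'`` negates y.  Charges and atom identities are untouched,
    so any chiral arrangement has its handedness inverted.  Reflection
    about 0 is exact in floating point, which keeps mirror-antisymmetry
    checks at machine precision.
    """
    axis = {"yz": 0, "xz": 1, "xy": 2}[plane]
    out = frame.copy()
    out.positions[:, axis] = 2.0 * about - out.positions[:, axis]
    return out


def orthorhombic_box(lx: float, ly: float, lz: float) -> np.ndarray:
    return np.diag([float(lx), float(ly), float(lz)])
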