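"""Fixture generators: rigid waters, chiral helices, slabs, and a
charged-site strand mimic.

Every generator is a pure function of its parameters and seed, so all
fixtures are bit-reproducible.  Geometry and charges of the 4-site water
come from the shipped TIP4P-Ew table; the strand mimic is an idealized
extended beta-strand presenting backbone C=O / N-H sites and ammonium-like
charged side-chain sites to the water phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .system import (Frame, Subset, Topology, orthorhombic_box, reflect_frame,
                     ROLE_O, ROLE_H1, ROLE_H2, ROLE_VIRTUAL, ROLE_NA)

_E_A_TO_DEBYE = 4.80320425  # 1 e*Angstrom in Debye


def _load_water_table() -> dict:
    with resources.files("chiralsfg.data").joinpath("charges_tip4pew.json").open() as fh:
        return json.load(fh)


@dataclass
class WaterTemplate:
    """Rigid 3/4-site water geometry and charges.

    The local frame has O at the origin, the HOH bisector along +z
    (hydrogens on the +z side) and both O-H bonds in the xz plane.
    A nonzero ``virtual_site_offset`` places an M-type charge site on
    the bisector (4-site models).
    """

    r_OH: float = 0.9572
    theta_HOH: float = 104.52
    site_charges: dict = field(default_factory=lambda: {
        "O": 0.0, "H1": 0.52422, "H2": 0.52422, "virtual": -1.04844})
    virtual_site_offset: float = 0.125

    @classmethod
    def tip4pew(cls) -> "WaterTemplate":
        tab = _load_water_table()
        g = tab["geometry"]
        return cls(r_OH=g["r_OH"], theta_HOH=g["theta_HOH"],
                   site_charges=dict(tab["charges"]),
                   virtual_site_offset=g["virtual_site_offset"])

    @property
    def has_virtual(self) -> bool:
        return self.virtual_site_offset > 0.0

    @property
    def n_sites(self) -> int:
        return 4 if self.has_virtual else 3

    def local_coordinates(self) -> np.ndarray:
        """(n_sites, 3) local positions in order O, H1, H2[, M]."""
        half = np.deg2rad(self.theta_HOH) / 2.0
        s, c = np.sin(half), np.cos(half)
        coords = [np.zeros(3),
                  np.array([self.r_OH * s, 0.0, self.r_OH * c]),
                  np.array([-self.r_OH * s, 0.0, self.r_OH * c])]
        if self.has_virtual:
            coords.append(np.array([0.0, 0.0, self.virtual_site_offset]))
        return np.array(coords)

    def gas_phase_dipole_debye(self) -> float:
        """Magnitude of the point-charge dipole of one template water."""
        q = self.charge_array()
        mu = -(self.local_coordinates() * q[:, None]).sum(axis=0)
        return float(np.linalg.norm(mu)) * _E_A_TO_DEBYE

    def charge_array(self) -> np.ndarray:
        keys = ["O", "H1", "H2"] + (["virtual"] if self.has_virtual else [])
        return np.array([self.site_charges[k] for k in keys])

    def site_roles(self) -> list[str]:
        return [ROLE_O, ROLE_H1, ROLE_H2] + ([ROLE_VIRTUAL] if self.has_virtual else [])


def make_water(center: np.ndarray, rotation: np.ndarray,
               template: WaterTemplate | None = None) -> np.ndarray:
    """Place one rigid water: returns (n_sites, 3) lab-frame positions.

    ``rotation`` is a proper 3x3 rotation matrix applied to the template's
    local coordinates before translating to ``center``.
    """
    template = template or WaterTemplate.tip4pew()
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-8:
        raise ValueError("rotation must be a proper 3x3 rotation matrix")
    return np.asarray(center, dtype=float) + template.local_coordinates() @ R.T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rotation_from_axes(x_axis: np.ndarray, z_axis: np.ndarray) -> np.ndarray:
    """Rotation whose columns map local x/z to the given lab directions."""
    ez = np.asarray(z_axis, float)
    ez = ez / np.linalg.norm(ez)
    ex = np.asarray(x_axis, float)
    ex = ex - ez * (ex @ ez)
    ex = ex / np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    return np.column_stack([ex, ey, ez])


# ---------------------------------------------------------------------------
# Topology assembly
# ---------------------------------------------------------------------------

def water_topology(n_waters: int, template: WaterTemplate | None = None,
                   residue_name: str = "HOH", first_mol_id: int = 0,
                   first_residue: int = 1) -> Topology:
    """Topology of ``n_waters`` identical template waters (no solute)."""
    template = template or WaterTemplate.tip4pew()
    roles = template.site_roles()
    names = {ROLE_O: "OW", ROLE_H1: "HW1", ROLE_H2: "HW2", ROLE_VIRTUAL: "MW"}
    elems = {ROLE_O: "O", ROLE_H1: "H", ROLE_H2: "H", ROLE_VIRTUAL: ""}
    q = template.charge_array()
    n_sites = template.n_sites
    n = n_waters * n_sites
    return Topology(
        atom_name=np.array([names[r] for _ in range(n_waters) for r in roles]),
        residue_name=np.array([residue_name] * n),
        residue_index=np.array([first_residue + i for i in range(n_waters)
                                for _ in roles]),
        element=np.array([elems[r] for _ in range(n_waters) for r in roles]),
        partial_charge=np.tile(q, n_waters),
        molecule_id=np.array([first_mol_id + i for i in range(n_waters)
                              for _ in roles]),
        is_water=np.ones(n, dtype=bool),
        water_site_role=np.array([r for _ in range(n_waters) for r in roles]),
    )


def concatenate_topologies(a: Topology, b: Topology) -> Topology:
    return Topology(
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        residue_name=np.concatenate([a.residue_name, b.residue_name]),
        residue_index=np.concatenate([a.residue_index, b.residue_index]),
        element=np.concatenate([a.element, b.element]),
        partial_charge=np.concatenate([a.partial_charge, b.partial_charge]),
        molecule_id=np.concatenate([a.molecule_id, b.molecule_id]),
        is_water=np.concatenate([a.is_water, b.is_water]),
        water_site_role=np.concatenate([a.water_site_role, b.water_site_role]),
    )


def frame_from_waters(water_positions: Sequence[np.ndarray], box: np.ndarray,
                      vacuum_axis: str = "z", time: float = 0.0) -> Frame:
    return Frame(np.vstack(water_positions), np.asarray(box, float),
                 vacuum_axis, time)


# ---------------------------------------------------------------------------
# Mirror constructions
# ---------------------------------------------------------------------------

def build_mirror_pair(frame: Frame, plane: str = "yz") -> Frame:
    """Mirror image of a frame through a vertical plane ('yz' or 'xz').

    The plane must contain the interface normal (vacuum axis), so any
    chiral arrangement has its handedness inverted while the interface
    geometry is preserved.  Reflection is exact (an involution).
    """
    if plane not in ("yz", "xz"):
        raise ValueError("plane must be 'yz' or 'xz' (vertical planes)")
    axis = {"yz": "x", "xz": "y"}[plane]
    if axis == frame.vacuum_axis:
        raise ValueError("mirror plane must be perpendicular to the interface")
    return reflect_frame(frame, plane)


def build_mirror_symmetric_cluster(n_pairs: int, seed: int = 0,
                                   box_edge: float = 40.0,
                                   template: WaterTemplate | None = None
                                   ) -> tuple[Topology, Frame]:
    """Waters placed as exact mirror pairs across the yz plane.

    Each random water at +x gets a partner that is its literal reflection,
    so the configuration has an exact vertical mirror plane: its chiral
    chi2_zyx response cancels pair by pair to floating-point exactness.
    """
    template = template or WaterTemplate.tip4pew()
    rng = np.random.default_rng(seed)
    waters = []
    for _ in range(n_pairs):
        center = np.array([rng.uniform(3.0, box_edge / 2 - 3.0),
                           rng.uniform(-box_edge / 2 + 3.0, box_edge / 2 - 3.0),
                           rng.uniform(-8.0, 8.0)])
        pos = make_water(center, random_rotation(rng), template)
        mirrored = pos.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        waters.extend([pos, mirrored])
    topo = water_topology(2 * n_pairs, template)
    box = orthorhombic_box(box_edge, box_edge, 3 * box_edge)
    frame = frame_from_waters(waters, box)
    frame.positions[:, :2] += box_edge / 2.0  # center the cluster in the box
    frame.positions[:, 2] += 1.5 * box_edge / 2.0
    return topo, frame


def build_chiral_water_helix(n: int, radius: float = 5.0, pitch: float = 4.0,
                             handedness: int = 1, dipole_tilt: float = 30.0,
                             twist: float = 40.0,
                             template: WaterTemplate | None = None,
                             box_edge: float | None = None
                             ) -> tuple[Topology, Frame]:
    """Waters on a helix with orientations that break all vertical mirrors.

    Each water sits at azimuth 2*pi*k/n and height k*pitch/n with its
    dipole (HOH bisector) pointing inward, tilted up by ``dipole_tilt``
    degrees, and its molecular plane twisted about the bisector by
    ``twist`` degrees.  The twist breaks every vertical mirror plane, so
    the arrangement is chiral for handedness != 0.  ``handedness=-1`` is
    defined as the exact yz-plane mirror image of the +1 helix, which is
    the left-handed arrangement.  ``handedness=0`` gives a planar ring
    with untwisted, radial molecular planes: an explicitly achiral
    (vertical-mirror-symmetric) control.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    if handedness not in (-1, 0, 1):
        raise ValueError("handedness must be -1, 0, or +1")
    template = template or WaterTemplate.tip4pew()
    alpha = np.deg2rad(dipole_tilt)
    chi = np.deg2rad(twist) if handedness != 0 else 0.0
    waters = []
    for k in range(n):
        phi = 2.0 * np.pi * k / n
        rhat = np.array([np.cos(phi), np.sin(phi), 0.0])
        that = np.array([-np.sin(phi), np.cos(phi), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        bis = -np.cos(alpha) * rhat + np.sin(alpha) * zhat   # dipole axis
        u0 = np.sin(alpha) * rhat + np.cos(alpha) * zhat     # in vertical plane
        u = np.cos(chi) * u0 + np.sin(chi) * that
        z = (k * pitch / n) if handedness != 0 else 0.0
        center = radius * rhat + np.array([0.0, 0.0, z])
        waters.append(make_water(center, rotation_from_axes(u, bis), template))
    topo = water_topology(n, template)
    edge = box_edge or max(6.0 * radius, 30.0)
    frame = frame_from_waters(waters, orthorhombic_box(edge, edge, 3 * edge))
    frame.positions[:, :2] += edge / 2.0
    frame.positions[:, 2] += edge / 2.0
    if handedness == -1:
        frame = reflect_frame(frame, "yz", about=edge / 2.0)
    return topo, frame


# ---------------------------------------------------------------------------
# Slab fixtures
# ---------------------------------------------------------------------------

_VOL_PER_WATER = 29.92  # Angstrom^3 at 0.997 g/cm^3


def _place_waters_in_slab(n: int, lx: float, ly: float, z_lo: float,
                          z_hi: float, rng: np.random.Generator,
                          min_oo: float = 2.4,
                          forbidden: np.ndarray | None = None,
                          min_forbidden: float = 2.4,
                          max_attempts_per_water: int = 4000) -> np.ndarray:
    """Rejection-sampled oxygen positions with a minimum O-O distance."""
    box = np.array([lx, ly, 0.0])
    placed: list[np.ndarray] = []
    for i in range(n):
        for attempt in range(max_attempts_per_water):
            p = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                          rng.uniform(z_lo, z_hi)])
            ok = True
            if placed:
                d = np.asarray(placed) - p
                d[:, 0] -= lx * np.round(d[:, 0] / lx)
                d[:, 1] -= ly * np.round(d[:, 1] / ly)
                if np.min(np.einsum("ij,ij->i", d, d)) < min_oo ** 2:
                    ok = False
            if ok and forbidden is not None and len(forbidden):
                d = forbidden - p
                d[:, 0] -= lx * np.round(d[:, 0] / lx)
                d[:, 1] -= ly * np.round(d[:, 1] / ly)
                if np.min(np.einsum("ij,ij->i", d, d)) < min_forbidden ** 2:
                    ok = False
            if ok:
                placed.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place water {i + 1}/{n} after "
                f"{max_attempts_per_water} attempts; slab too dense")
    return np.asarray(placed)


def build_slab_fixture(n_waters: int, box: tuple[float, float, float] | None = None,
                       thermalize: bool = False, seed: int = 0,
                       template: WaterTemplate | None = None,
                       n_frames: int = 1,
                       equilibration_sweeps: int = 6000,
                       sweeps_per_frame: int = 30,
                       temperature: float = 298.0
                       ) -> tuple[Topology, list[Frame]]:
    """Water slab with vacuum along z.

    Without thermalization, oxygens are rejection-sampled at liquid
    density (2.4 Angstrom minimum O-O distance) with uniform random
    orientations, and ``n_frames`` identical frames are returned
    (deterministic in ``seed``).  With ``thermalize=True`` the in-package
    canonical Monte Carlo sampler (`chiralsfg.montecarlo`) equilibrates
    the slab at ``temperature`` and returns ``n_frames`` decorrelated
    frames, tagged 1 ps apart.
    """
    template = template or WaterTemplate.tip4pew()
    if box is None:
        t = (n_waters * _VOL_PER_WATER) ** (1.0 / 3.0)
        lx = ly = t
        lz = 2.0 * t
    else:
        lx, ly, lz = box
        t = n_waters * _VOL_PER_WATER / (lx * ly)
        if t > lz - 4.0:
            raise ValueError("box too small for n_waters at liquid density")
    z_lo, z_hi = lz / 2.0 - t / 2.0, lz / 2.0 + t / 2.0
    rng = np.random.default_rng(seed)
    o_pos = _place_waters_in_slab(n_waters, lx, ly, z_lo, z_hi, rng)
    rotations = np.array([random_rotation(rng) for _ in range(n_waters)])
    topo = water_topology(n_waters, template)
    box_vec = orthorhombic_box(lx, ly, lz)

    if not thermalize:
        pos = np.vstack([make_water(o_pos[i], rotations[i], template)
                         for i in range(n_waters)])
        return topo, [Frame(pos.copy(), box_vec, "z", float(k))
                      for k in range(n_frames)]

    from .montecarlo import WaterSlabSampler
    sampler = WaterSlabSampler(o_pos, rotations, (lx, ly, lz),
                               template=template, temperature=temperature,
                               rng=np.random.default_rng(seed + 1))
    sampler.run(equilibration_sweeps)
    frames = []
    for k in range(n_frames):
        sampler.run(sweeps_per_frame)
        frames.append(Frame(sampler.site_positions().reshape(-1, 3).copy(),
                            box_vec, "z", float(k)))
    return topo, frames


# ---------------------------------------------------------------------------
# Strand mimic
# ---------------------------------------------------------------------------

@dataclass
class TemplateStrand:
    """Idealized extended-strand mimic with point-charge interaction sites.

    Per residue: a backbone carbonyl (C=O) and amide (N-H) pair with
    opposed orientations alternating along the strand, plus an
    ammonium-like charged side-chain group (net +1) on every
    ``nh3_every``-th residue, displaced toward the water phase.  All
    backbone sites lie in a plane at ``depth`` Angstrom below the vacuum
    interface.
    """

    n_residues: int = 7
    spacing: float = 3.5
    depth: float = 2.0
    nh3_every: int = 2
    charge_scale: float = 1.0
    q_C: float = 0.51
    q_O: float = -0.51
    q_N: float = -0.51
    q_H: float = 0.51
    q_N3: float = -0.30
    q_H3: float = 1.30 / 3.0

    @property
    def n_nh3(self) -> int:
        return len(range(0, self.n_residues, self.nh3_every))

    @property
    def net_charge(self) -> float:
        return self.charge_scale * self.n_nh3 * (self.q_N3 + 3 * self.q_H3)

    def sites(self) -> tuple[np.ndarray, np.ndarray, list[str], list[int]]:
        """Returns (positions relative to strand origin, charges, names,
        residue indices).  Backbone sites (BBC/BBO/BBN/BBH) in the z=0
        plane; ammonium groups (SCN/SCH1-3) at z=-2.5 (toward water).
        Names are kept to 4 characters so they survive PDB round trips."""
        pos, q, names, res = [], [], [], []
        for i in range(self.n_residues):
            x = i * self.spacing
            sgn = 1.0 if i % 2 == 0 else -1.0
            pos += [np.array([x, 0.0, 0.0]),
                    np.array([x, sgn * 1.23, 0.0]),
                    np.array([x + 0.5 * self.spacing, -sgn * 0.8, 0.0]),
                    np.array([x + 0.5 * self.spacing, -sgn * 1.8, 0.0])]
            q += [self.q_C, self.q_O, self.q_N, self.q_H]
            names += ["BBC", "BBO", "BBN", "BBH"]
            res += [i] * 4
            if i % self.nh3_every == 0:
                base = np.array([x, 0.0, -2.5])
                pos.append(base)
                q.append(self.q_N3)
                names.append("SCN")
                res.append(i)
                for k in range(3):
                    ang = 2 * np.pi * k / 3
                    pos.append(base + np.array([0.47 * np.cos(ang),
                                                0.47 * np.sin(ang), -0.88]))
                    q.append(self.q_H3)
                    names.append(f"SCH{k + 1}")
                    res.append(i)
        return (np.asarray(pos), self.charge_scale * np.asarray(q),
                names, res)

    def topology(self, first_mol_id: int = 100000) -> Topology:
        _, q, names, res = self.sites()
        n = len(names)
        return Topology(
            atom_name=np.array(names),
            residue_name=np.array(["STR"] * n),
            residue_index=np.array(res) + 1,
            element=np.array([nm[2] for nm in names]),
            partial_charge=q,
            molecule_id=np.array([first_mol_id + r for r in res]),
            is_water=np.zeros(n, dtype=bool),
            water_site_role=np.array([ROLE_NA] * n),
        )


def build_template_system(strand: TemplateStrand | None = None,
                          n_waters: int = 80, seed: int = 0,
                          box: tuple[float, float, float] | None = None,
                          template: WaterTemplate | None = None,
                          thermalize: bool = False,
                          n_frames: int = 1,
                          equilibration_sweeps: int = 3000,
                          sweeps_per_frame: int = 30,
                          temperature: float = 298.0
                          ) -> tuple[Topology, list[Frame]]:
    """Strand mimic embedded at the upper interface of a water slab.

    The strand's backbone plane sits ``strand.depth`` below the slab's
    upper (vacuum-facing) surface; its charged side-chain sites point
    down into the water.  Waters fill the slab below, rejection-sampled
    around the strand sites.  With ``thermalize=True`` the waters are
    Monte-Carlo equilibrated in the strand's frozen external field.
    """
    strand = strand or TemplateStrand()
    template = template or WaterTemplate.tip4pew()
    rng = np.random.default_rng(seed)
    rel_pos, charges, _, _ = strand.sites()
    extent_x = rel_pos[:, 0].max() - rel_pos[:, 0].min()
    extent_y = rel_pos[:, 1].max() - rel_pos[:, 1].min()
    if box is None:
        lx = max(extent_x + 8.0, 14.0)
        ly = max(extent_y + 8.0, 14.0)
        t = n_waters * _VOL_PER_WATER / (lx * ly)
        lz = 2.0 * (t + 8.0)
    else:
        lx, ly, lz = box
        t = n_waters * _VOL_PER_WATER / (lx * ly)
    z_lo, z_hi = lz / 2.0 - t / 2.0, lz / 2.0 + t / 2.0
    # the vacuum interface is the top of the strand layer; the strand's
    # backbone plane sits `depth` below it, just above the water surface
    z_interface = z_hi + 3.0
    z_strand = z_interface - strand.depth
    origin = np.array([(lx - extent_x) / 2.0, ly / 2.0, z_strand])
    strand_pos = rel_pos + origin

    o_pos = _place_waters_in_slab(n_waters, lx, ly, z_lo,
                                  min(z_hi, z_strand - 0.8), rng,
                                  forbidden=strand_pos, min_forbidden=2.4)
    rotations = np.array([random_rotation(rng) for _ in range(n_waters)])
    strand_topo = strand.topology()
    water_topo = water_topology(n_waters, template)
    topo = concatenate_topologies(strand_topo, water_topo)
    box_vec = orthorhombic_box(lx, ly, lz)

    def assemble(opos, rots):
        waters = np.vstack([make_water(opos[i], rots[i], template)
                            for i in range(n_waters)])
        return np.vstack([strand_pos, waters])

    if not thermalize:
        pos = assemble(o_pos, rotations)
        return topo, [Frame(pos.copy(), box_vec, "z", float(k))
                      for k in range(n_frames)]

    from .montecarlo import WaterSlabSampler
    sampler = WaterSlabSampler(o_pos, rotations, (lx, ly, lz),
                               template=template, temperature=temperature,
                               external_positions=strand_pos,
                               external_charges=charges,
                               rng=np.random.default_rng(seed + 1))
    sampler.run(equilibration_sweeps)
    frames = []
    for k in range(n_frames):
        sampler.run(sweeps_per_frame)
        water_sites = sampler.site_positions().reshape(-1, 3)
        frames.append(Frame(np.vstack([strand_pos, water_sites]),
                            box_vec, "z", float(k)))
    return topo, frames
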