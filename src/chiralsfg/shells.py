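"""Voronoi hydration shells and hydrogen-bond taxonomy.

The first hydration shell is the set of water molecules with at least
one atom whose Voronoi cell shares a face with a solute atom's cell; the
second shell borders the first.  Tessellation is the standard unweighted
Voronoi of atomic centers (virtual charge sites excluded) with full
periodic boundary conditions, realized by tiling the cell with its 26
periodic images and tessellating with qhull.  Hydrogen bonds use the
geometric criteria: donor-acceptor heavy-atom distance below 3.5 A and
donor-H...acceptor angle at the hydrogen above 135 degrees (180 =
linear); the angle is measured at the H because only there does a
">135 deg" threshold make geometric sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import Voronoi

from .system import Frame, Topology, minimum_image_displacements


@dataclass
class HBondCriteria:
    heavy_distance_max: float = 3.5   # Angstrom
    angle_min: float = 135.0          # degrees, at the H; 180 = linear
    strong_H_to_O_max: float = 1.6    # Angstrom, H...acceptor-O

    def __post_init__(self):
        if min(self.heavy_distance_max, self.angle_min,
               self.strong_H_to_O_max) <= 0 or self.angle_min > 180:
            raise ValueError("invalid H-bond criteria")


@dataclass
class HBond:
    donor_heavy: int
    donor_h: int
    acceptor: int
    distance: float      # heavy-heavy, Angstrom
    angle: float         # degrees at H
    h_to_acceptor: float # Angstrom


@dataclass
class ShellAssignment:
    first_shell: set = field(default_factory=set)
    second_shell: set = field(default_factory=set)
    backbone_region: set = field(default_factory=set)
    sidechain_region: set = field(default_factory=set)
    hb_to_CO: set = field(default_factory=set)
    hb_to_NH: set = field(default_factory=set)
    hb_to_NH3: set = field(default_factory=set)
    strong_hb_CO: set = field(default_factory=set)
    backbone_no_hb: set = field(default_factory=set)
    sidechain_no_hb: set = field(default_factory=set)

    def as_dict(self) -> dict[str, set]:
        return {k: getattr(self, k) for k in (
            "first_shell", "second_shell", "backbone_region",
            "sidechain_region", "hb_to_CO", "hb_to_NH", "hb_to_NH3",
            "strong_hb_CO", "backbone_no_hb", "sidechain_no_hb")}


# ---------------------------------------------------------------------------
# Periodic Voronoi neighbors
# ---------------------------------------------------------------------------

def _ridge_area(vor: Voronoi, vertex_ids) -> float:
    if -1 in vertex_ids:
        return np.inf  # unbounded ridge (cannot happen for interior cells)
    verts = vor.vertices[vertex_ids]
    c = verts.mean(axis=0)
    area = 0.0
    for k in range(len(verts)):
        a, b = verts[k] - c, verts[(k + 1) % len(verts)] - c
        area += 0.5 * np.linalg.norm(np.cross(a, b))
    return area


def voronoi_neighbors(frame: Frame, topology: Topology,
                      min_face_area: float = 1e-6,
                      image_buffer: float = 14.0) -> dict[int, set[int]]:
    """Face-sharing Voronoi neighbor map of atoms under periodic boundaries.

    Virtual (massless charge) sites are excluded from the tessellation.
    Faces with area below ``min_face_area`` (Angstrom^2) are dropped:
    they are numerical slivers from degenerate arrangements (e.g. exact
    lattices, which are additionally stabilized by a deterministic
    1e-9 A jitter retry if qhull rejects the input).
    """
    real = np.flatnonzero(topology.water_site_role != "virtual")
    if len(real) < 2:
        raise ValueError("need at least 2 non-virtual atoms")
    pos = frame.positions[real]
    box = frame.box_vectors
    # wrap into the primary cell, then tile with the 26 periodic images
    frac = pos @ np.linalg.inv(box)
    frac -= np.floor(frac)
    pos0 = frac @ box
    _check_coincident(pos0, box, real)
    tiles = [pos0]
    index_map = [np.arange(len(real))]
    lo, hi = -image_buffer, image_buffer
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                if sx == sy == sz == 0:
                    continue
                shift = sx * box[0] + sy * box[1] + sz * box[2]
                img = pos0 + shift
                keep = np.all((img > lo) &
                              (img < box.sum(axis=0) + hi), axis=1)
                if np.any(keep):
                    tiles.append(img[keep])
                    index_map.append(np.flatnonzero(keep))
    points = np.vstack(tiles)
    owner = np.concatenate(index_map)          # local (within `real`) index
    n_central = len(real)
    try:
        vor = Voronoi(points)
    except Exception:
        rng = np.random.default_rng(1905)
        warnings.warn("degenerate point set; retrying Voronoi with 1e-9 A jitter")
        vor = Voronoi(points + rng.normal(0.0, 1e-9, points.shape))
    neighbors: dict[int, set[int]] = {int(real[i]): set()
                                      for i in range(n_central)}
    for (p, q), vids in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_central and q >= n_central:
            continue
        if _ridge_area(vor, vids) <= min_face_area:
            continue
        a, b = int(owner[p]), int(owner[q])
        if a == b:
            continue
        neighbors[int(real[a])].add(int(real[b]))
        neighbors[int(real[b])].add(int(real[a]))
    return neighbors


def _check_coincident(pos: np.ndarray, box: np.ndarray, real: np.ndarray):
    # cheap exact-duplicate check (degenerate tessellation input)
    _, counts = np.unique(np.round(pos, 6), axis=0, return_counts=True)
    if np.any(counts > 1):
        rounded = np.round(pos, 6)
        _, inv, cts = np.unique(rounded, axis=0, return_inverse=True,
                                return_counts=True)
        dup = real[np.isin(inv, np.flatnonzero(cts > 1))]
        raise ValueError(f"coincident atoms in tessellation input: {dup.tolist()}")


def assign_shells(neighbors: dict[int, set[int]], topology: Topology
                  ) -> tuple[set[int], set[int]]:
    """First and second hydration shells (sets of water molecule ids)."""
    solute = set(int(i) for i in topology.solute_atom_indices())
    if not solute:
        raise ValueError("no solute atoms present")
    mol = topology.molecule_id
    water_atoms = np.flatnonzero(topology.is_water &
                                 (topology.water_site_role != "virtual"))
    first: set[int] = set()
    for a in water_atoms:
        if neighbors.get(int(a), set()) & solute:
            first.add(int(mol[a]))
    first_atoms = {int(a) for a in water_atoms if int(mol[a]) in first}
    second: set[int] = set()
    for a in water_atoms:
        m = int(mol[a])
        if m in first:
            continue
        if neighbors.get(int(a), set()) & first_atoms:
            second.add(m)
    return first, second


DEFAULT_BACKBONE_NAMES = {"BBC", "BBO", "BBN", "BBH",
                          "C", "O", "N", "H", "CA", "HA", "HA2", "HA3"}
DEFAULT_SIDECHAIN_PREFIXES = ("SCN", "SCH", "CB", "CG", "CD", "CE", "NZ",
                              "HZ", "HB", "HG", "HD", "HE")


def default_solute_class(name: str) -> str | None:
    name = str(name).strip()
    if name in DEFAULT_BACKBONE_NAMES:
        return "backbone"
    if any(name.startswith(p) for p in DEFAULT_SIDECHAIN_PREFIXES):
        return "sidechain"
    return None


def split_backbone_sidechain(first_shell: set[int],
                             neighbors: dict[int, set[int]],
                             topology: Topology,
                             classify: Callable[[str], str | None] | None = None
                             ) -> tuple[set[int], set[int]]:
    """Backbone/side-chain regions of the first shell by Voronoi contact.

    A water touching both solute classes belongs to both regions (the
    deliberate overlap), so every first-shell water is covered.
    """
    classify = classify or default_solute_class
    solute = topology.solute_atom_indices()
    classes = {}
    unlabeled = []
    for a in solute:
        c = classify(topology.atom_name[a])
        if c is None:
            unlabeled.append(str(topology.atom_name[a]))
        classes[int(a)] = c
    if unlabeled:
        raise ValueError(f"unlabeled solute atoms: {sorted(set(unlabeled))}")
    mol = topology.molecule_id
    water_atoms = np.flatnonzero(topology.is_water &
                                 (topology.water_site_role != "virtual"))
    backbone, sidechain = set(), set()
    for a in water_atoms:
        m = int(mol[a])
        if m not in first_shell:
            continue
        for nb in neighbors.get(int(a), set()):
            c = classes.get(int(nb))
            if c == "backbone":
                backbone.add(m)
            elif c == "sidechain":
                sidechain.add(m)
    return backbone, sidechain


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class SiteRules:
    """Donor (heavy, H) index pairs and acceptor heavy-atom indices."""
    donor_pairs: list[tuple[int, int]]
    acceptors: list[int]


def default_site_rules(topology: Topology) -> SiteRules:
    """Waters: O-H1/O-H2 donors, O acceptor.  Solute: amide (BBN-BBH) and
    ammonium (SCN-SCH*) pairs donate; O atoms accept.  Amide N and the
    protonated ammonium N are not acceptors (no accessible lone pair)."""
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for m in topology.water_molecule_ids():
        s = topology.water_sites(int(m))
        donors += [(s["O"], s["H1"]), (s["O"], s["H2"])]
        acceptors.append(s["O"])
    solute = topology.solute_atom_indices()
    for a in solute:
        if str(topology.element[a]).upper() == "O":
            acceptors.append(int(a))
    # pair each solute H with the last same-prefix N/O heavy atom of its residue
    for a in solute:
        name = str(topology.atom_name[a])
        if str(topology.element[a]).upper() != "H":
            continue
        res = topology.residue_index[a]
        prefix = name[:2]
        cands = [int(b) for b in solute
                 if topology.residue_index[b] == res and b != a
                 and str(topology.element[b]).upper() in ("N", "O")
                 and str(topology.atom_name[b]).startswith(prefix)]
        if cands:
            donors.append((cands[-1], int(a)))
    return SiteRules(donors, acceptors)


def detect_hbonds(frame: Frame, topology: Topology,
                  criteria: HBondCriteria | None = None,
                  rules: SiteRules | None = None) -> list[HBond]:
    """Geometric hydrogen bonds under minimum image."""
    criteria = criteria or HBondCriteria()
    rules = rules or default_site_rules(topology)
    if not rules.donor_pairs or not rules.acceptors:
        return []
    pos = frame.positions
    box = frame.box_vectors
    mol = topology.molecule_id
    heavies = np.array([d for d, _ in rules.donor_pairs])
    hs = np.array([h for _, h in rules.donor_pairs])
    acc = np.asarray(rules.acceptors)
    cos_min = np.cos(np.deg2rad(criteria.angle_min))
    out: list[HBond] = []
    # heavy-heavy distance matrix (n_donors, n_acceptors)
    d_da = pos[acc][None, :, :] - pos[heavies][:, None, :]
    d_da = minimum_image_displacements(d_da, box)
    r_da = np.linalg.norm(d_da, axis=-1)
    same_mol = mol[heavies][:, None] == mol[acc][None, :]
    cand = np.argwhere((r_da < criteria.heavy_distance_max) & ~same_mol)
    for di, ai in cand:
        d_idx, h_idx, a_idx = int(heavies[di]), int(hs[di]), int(acc[ai])
        v_hd = minimum_image_displacements(pos[d_idx] - pos[h_idx], box)
        v_ha = minimum_image_displacements(pos[a_idx] - pos[h_idx], box)
        r_ha = np.linalg.norm(v_ha)
        cosang = float(v_hd @ v_ha) / (np.linalg.norm(v_hd) * r_ha)
        # angle at H: 180 deg = linear D-H...A, i.e. cos(angle) <= cos(angle_min)
        if cosang <= cos_min:
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            out.append(HBond(d_idx, h_idx, a_idx, float(r_da[di, ai]),
                             ang, float(r_ha)))
    return out


def classify_first_shell(first_shell: set[int], hbonds: list[HBond],
                         backbone_region: set[int], sidechain_region: set[int],
                         topology: Topology,
                         criteria: HBondCriteria | None = None,
                         second_shell: set[int] | None = None
                         ) -> ShellAssignment:
    """Populate the first-shell H-bond taxonomy.

    Water donating to a backbone carbonyl O -> hb_to_CO (strong subset by
    H...O distance); water accepting from a backbone amide N-H ->
    hb_to_NH; water H-bonded to the charged side-chain ammonium (either
    direction) -> hb_to_NH3; backbone/side-chain waters with no H-bond to
    that solute class -> *_no_hb.
    """
    criteria = criteria or HBondCriteria()
    mol = topology.molecule_id
    name = topology.atom_name
    is_w = topology.is_water
    asn = ShellAssignment(first_shell=set(first_shell),
                          second_shell=set(second_shell or set()),
                          backbone_region=set(backbone_region),
                          sidechain_region=set(sidechain_region))
    bb_hb: set[int] = set()
    sc_hb: set[int] = set()
    for hb in hbonds:
        don_w = bool(is_w[hb.donor_h])
        acc_w = bool(is_w[hb.acceptor])
        if don_w and not acc_w:
            w = int(mol[hb.donor_h])
            an = str(name[hb.acceptor])
            cls = default_solute_class(an)
            if cls == "backbone":
                bb_hb.add(w)
                if an in ("BBO", "O"):
                    asn.hb_to_CO.add(w)
                    if hb.h_to_acceptor <= criteria.strong_H_to_O_max:
                        asn.strong_hb_CO.add(w)
            elif cls == "sidechain":
                sc_hb.add(w)
                if an.startswith(("SCN", "NZ")):
                    asn.hb_to_NH3.add(w)
        elif acc_w and not don_w:
            w = int(mol[hb.acceptor])
            dn = str(name[hb.donor_h])
            cls = default_solute_class(dn)
            if cls == "backbone":
                bb_hb.add(w)
                if dn.startswith(("BBH", "H")):
                    asn.hb_to_NH.add(w)
            elif cls == "sidechain":
                sc_hb.add(w)
                if dn.startswith(("SCH", "HZ")):
                    asn.hb_to_NH3.add(w)
    asn.hb_to_CO &= first_shell
    asn.hb_to_NH &= first_shell
    asn.hb_to_NH3 &= first_shell
    asn.strong_hb_CO &= first_shell
    asn.backbone_no_hb = asn.backbone_region - bb_hb
    asn.sidechain_no_hb = asn.sidechain_region - sc_hb
    return asn
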