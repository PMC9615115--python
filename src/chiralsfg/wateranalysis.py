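"""Water-ordering diagnostics: dipoles, H-bond counts, retention times,
interfacial dipole grids, annulus profiles, mirror-asymmetry scores and
dangling-OH fractions.

Dipole convention: the molecular dipole vector bisects the H-O-H angle
and points toward the oxygen (so it is the negative of the point-charge
sum about the oxygen).  The interfacial plane is perpendicular to the
vacuum axis; the instantaneous water surface is located as the mean
height of the top decile of water oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .shells import HBondCriteria, SiteRules, default_site_rules, detect_hbonds
from .spectrum import SpectrumResult, band_area
from .system import AXIS_INDEX, Frame, Subset, Topology, minimum_image_displacements

E_A_TO_DEBYE = 4.80320425


# ---------------------------------------------------------------------------
# Dipoles
# ---------------------------------------------------------------------------

def water_dipole(frame: Frame, topology: Topology, molecule_id: int) -> np.ndarray:
    """Point-charge dipole (Debye) of one water, pointing toward the oxygen."""
    idx = topology.atoms_of_molecule(molecule_id)
    if not topology.is_water[idx].all():
        raise ValueError(f"molecule {molecule_id} is not a water")
    q = topology.partial_charge[idx]
    o_idx = idx[topology.water_site_role[idx] == "O"][0]
    rel = minimum_image_displacements(
        frame.positions[idx] - frame.positions[o_idx], frame.box_vectors)
    return -E_A_TO_DEBYE * np.sum(q[:, None] * rel, axis=0)


# ---------------------------------------------------------------------------
# H-bond counts
# ---------------------------------------------------------------------------

def hbond_counts_per_water(frame: Frame, topology: Topology,
                           criteria: HBondCriteria | None = None,
                           rules: SiteRules | None = None) -> dict[int, int]:
    """Donated + accepted H-bond count per water molecule, one frame."""
    rules = rules or default_site_rules(topology)
    counts = {int(m): 0 for m in topology.water_molecule_ids()}
    for hb in detect_hbonds(frame, topology, criteria, rules):
        for atom in (hb.donor_h, hb.acceptor):
            if topology.is_water[atom]:
                counts[int(topology.molecule_id[atom])] += 1
    return counts


def mean_hbonds_per_water(frames, topology: Topology,
                          subset: Subset | None = None,
                          criteria: HBondCriteria | None = None,
                          rules: SiteRules | None = None) -> float:
    """Frame- and molecule-averaged H-bonds per water for a subset
    (all waters if ``subset`` is None)."""
    rules = rules or default_site_rules(topology)
    total, n = 0.0, 0
    for fi, frame in enumerate(frames):
        counts = hbond_counts_per_water(frame, topology, criteria, rules)
        members = (counts.keys() if subset is None
                   else subset.members_per_frame[fi])
        for m in members:
            total += counts[int(m)]
            n += 1
    if n == 0:
        raise ValueError("subset empty in every frame")
    return total / n


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

@dataclass
class RetentionRecord:
    subset_name: str
    episode_durations: list[float]    # ps
    mean_retention: float             # ps
    n_censored: int                   # episodes truncated by an edge

    @property
    def n_episodes(self) -> int:
        return len(self.episode_durations)


def retention_times(membership: Subset, time_step: float = 1.0) -> RetentionRecord:
    """Mean arrival-to-exit duration of continuous subset membership.

    Episodes are maximal runs of consecutive frames in the subset; runs
    touching either trajectory edge are included in the mean and counted
    as censored.
    """
    frames = membership.members_per_frame
    if not frames or all(len(m) == 0 for m in frames):
        raise ValueError("empty membership")
    mols = sorted(set().union(*frames))
    n_frames = len(frames)
    durations: list[float] = []
    n_censored = 0
    for m in mols:
        run = 0
        for fi in range(n_frames):
            if m in frames[fi]:
                run += 1
            elif run:
                durations.append(run * time_step)
                if fi == run:  # run started at frame 0
                    n_censored += 1
                run = 0
        if run:
            durations.append(run * time_step)
            n_censored += 1
    return RetentionRecord(membership.name, durations,
                           float(np.mean(durations)), n_censored)


def signal_vs_retention(subsets: list[Subset],
                        spectra: dict[str, SpectrumResult],
                        retention: dict[str, RetentionRecord],
                        band: tuple[float, float] = (2800.0, 4000.0),
                        correlate: list[str] | None = None) -> pd.DataFrame:
    """Join per-water absolute chiral band area with mean retention.

    Returns one row per subset plus a Spearman rank correlation over the
    subsets named in ``correlate`` (default: all), stored in
    ``df.attrs['rank_correlation']``.
    """
    rows = []
    for s in subsets:
        if s.name not in spectra or s.name not in retention:
            raise KeyError(f"subset {s.name!r} missing a spectrum or retention")
        res = spectra[s.name]
        area = band_area(res, band[0], band[1], mode="absolute")
        if not res.per_water:
            if res.mean_subset_size <= 0:
                raise ValueError(f"empty subset {s.name!r}")
            area /= res.mean_subset_size
        rows.append({"subset": s.name, "per_water_band_area": area,
                     "mean_retention_ps": retention[s.name].mean_retention})
    df = pd.DataFrame(rows)
    names = correlate or [s.name for s in subsets]
    sel = df[df.subset.isin(names)]
    if len(sel) >= 2 and sel.per_water_band_area.nunique() > 1:
        rho = stats.spearmanr(sel.per_water_band_area,
                              sel.mean_retention_ps).statistic
    else:
        rho = np.nan
    df.attrs["rank_correlation"] = float(rho) if rho == rho else np.nan
    return df


# ---------------------------------------------------------------------------
# Dipole grids
# ---------------------------------------------------------------------------

@dataclass
class DipoleGrid:
    """Per-cell vector sums of water dipoles on the interfacial plane."""
    vectors: np.ndarray       # (nx, ny, 3), Debye (summed over frames)
    occupancy: np.ndarray     # (nx, ny) int
    resolution: float         # Angstrom
    origin: np.ndarray        # in-plane (2,) coordinates of cell (0,0) corner
    plane_axes: tuple[int, int]
    depth_range: tuple[float, float]

    def mean_field(self) -> np.ndarray:
        """Per-cell mean dipole; zero where unoccupied."""
        occ = np.maximum(self.occupancy, 1)[:, :, None]
        out = self.vectors / occ
        out[self.occupancy == 0] = 0.0
        return out

    def unit_field(self) -> np.ndarray:
        v = self.vectors.copy()
        norm = np.linalg.norm(v, axis=2, keepdims=True)
        nz = norm[:, :, 0] > 0
        v[nz] /= norm[nz]
        v[~nz] = 0.0
        return v

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.occupancy.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.resolution
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.resolution
        return cx, cy


def locate_interface(frame: Frame, topology: Topology,
                     top_fraction: float = 0.1) -> float:
    """Water-surface height: mean vacuum-axis coordinate of the top
    decile of water oxygens."""
    ax = AXIS_INDEX[frame.vacuum_axis]
    o_idx = np.flatnonzero(topology.is_water &
                           (topology.water_site_role == "O"))
    z = np.sort(frame.positions[o_idx, ax])
    k = max(1, int(np.ceil(top_fraction * len(z))))
    return float(np.mean(z[-k:]))


def dipole_grid(frames, topology: Topology, resolution: float = 1.0,
                depth_range: tuple[float, float] = (0.0, 14.0),
                interface: float | None = None) -> DipoleGrid:
    """Accumulate water dipoles on an in-plane grid, binned by the
    oxygen's in-plane coordinates, restricted to oxygens whose depth
    below the (per-frame) interface lies in ``depth_range``."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    frames = list(frames)
    f0 = frames[0]
    ax = AXIS_INDEX[f0.vacuum_axis]
    plane = tuple(i for i in range(3) if i != ax)
    lengths = np.linalg.norm(f0.box_vectors, axis=1)
    nx = int(np.ceil(lengths[plane[0]] / resolution))
    ny = int(np.ceil(lengths[plane[1]] / resolution))
    vectors = np.zeros((nx, ny, 3))
    occupancy = np.zeros((nx, ny), dtype=int)
    o_of = {int(m): topology.water_sites(int(m))["O"]
            for m in topology.water_molecule_ids()}
    for frame in frames:
        surf = locate_interface(frame, topology) if interface is None else interface
        for m, o_idx in o_of.items():
            p = frame.positions[o_idx]
            depth = surf - p[ax]
            if not (depth_range[0] <= depth <= depth_range[1]):
                continue
            ix = int(np.floor((p[plane[0]] % lengths[plane[0]]) / resolution))
            iy = int(np.floor((p[plane[1]] % lengths[plane[1]]) / resolution))
            ix, iy = min(ix, nx - 1), min(iy, ny - 1)
            vectors[ix, iy] += water_dipole(frame, topology, m)
            occupancy[ix, iy] += 1
    return DipoleGrid(vectors, occupancy, resolution, np.zeros(2), plane,
                      tuple(depth_range))


def annulus_dipole_profile(grid: DipoleGrid, center: tuple[float, float],
                           ring_width: float = 1.0) -> pd.DataFrame:
    """Magnitude of the vector sum of cell dipoles in concentric rings.

    Rings are [k*w, (k+1)*w) in the in-plane radial distance of cell
    centers from ``center``.  Both the full 3-vector-sum magnitude and
    the in-plane (2D) magnitude are reported.
    """
    if ring_width <= 0:
        raise ValueError("ring_width must be positive")
    cx, cy = grid.cell_centers()
    if not (cx[0] - grid.resolution <= center[0] <= cx[-1] + grid.resolution
            and cy[0] - grid.resolution <= center[1] <= cy[-1] + grid.resolution):
        raise ValueError("center outside grid")
    dx = cx[:, None] - center[0]
    dy = cy[None, :] - center[1]
    r = np.sqrt(dx ** 2 + dy ** 2)
    ring = np.floor(r / ring_width).astype(int)
    px, py = grid.plane_axes
    rows = []
    for k in range(int(ring.max()) + 1):
        mask = ring == k
        vsum = grid.vectors[mask].sum(axis=0)
        rows.append({
            "r_inner": k * ring_width, "r_outer": (k + 1) * ring_width,
            "n_cells": int(mask.sum()),
            "occupancy": int(grid.occupancy[mask].sum()),
            "magnitude": float(np.linalg.norm(vsum)),
            "magnitude_inplane": float(np.hypot(vsum[px], vsum[py])),
        })
    return pd.DataFrame(rows)


def mirror_asymmetry_score(grid: DipoleGrid, plane_axis: int,
                           plane_position: float) -> float:
    """RMS deviation of the per-cell mean dipole field from its mirror
    image across a vertical plane.

    ``plane_axis`` is the in-plane axis index (0 or 1 of the grid)
    perpendicular to the mirror plane.  The mirror image negates the
    dipole component along that axis.  Only cell pairs occupied on both
    sides enter; a mirror-symmetric field scores 0.
    """
    field_arr = grid.mean_field()
    occ = grid.occupancy
    cx, cy = grid.cell_centers()
    coords = cx if plane_axis == 0 else cy
    lab_axis = grid.plane_axes[plane_axis]
    # mirrored cell index: nearest cell to the reflected center
    mirrored = 2.0 * plane_position - coords
    if mirrored.max() < coords[0] or mirrored.min() > coords[-1]:
        raise ValueError("mirror plane outside grid bounds")
    origin = coords[0] - grid.resolution / 2.0
    pair_idx = np.floor((mirrored - origin) / grid.resolution).astype(int)
    valid = (pair_idx >= 0) & (pair_idx < len(coords))
    diffs = []
    nx, ny = occ.shape
    for i in range(nx):
        for j in range(ny):
            if plane_axis == 0:
                if not valid[i]:
                    continue
                mi, mj = pair_idx[i], j
            else:
                if not valid[j]:
                    continue
                mi, mj = i, pair_idx[j]
            if occ[i, j] == 0 or occ[mi, mj] == 0:
                continue
            mirror_v = field_arr[mi, mj].copy()
            mirror_v[lab_axis] = -mirror_v[lab_axis]
            diffs.append(field_arr[i, j] - mirror_v)
    if not diffs:
        raise ValueError("no occupied cell pairs across the plane")
    diffs_arr = np.asarray(diffs)
    return float(np.sqrt(np.mean(np.sum(diffs_arr ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Dangling OH
# ---------------------------------------------------------------------------

def dangling_oh_fraction(frames, topology: Topology, subset: Subset | None,
                         angle_max: float = 60.0,
                         criteria: HBondCriteria | None = None,
                         rules: SiteRules | None = None) -> float:
    """Fraction of subset waters with a free O-H pointing toward vacuum.

    An O-H qualifies when its angle to the vacuum-side interface normal
    is below ``angle_max`` degrees and its H donates no hydrogen bond;
    a water counts if at least one of its O-H groups qualifies.  Pooled
    over frames.
    """
    rules_cache = rules
    cos_max = np.cos(np.deg2rad(angle_max))
    counted, total = 0, 0
    for fi, frame in enumerate(frames):
        ax = AXIS_INDEX[frame.vacuum_axis]
        normal = np.zeros(3)
        normal[ax] = 1.0  # vacuum at +axis
        r = rules_cache or default_site_rules(topology)
        donating_h = {hb.donor_h for hb in detect_hbonds(frame, topology,
                                                         criteria, r)}
        members = (topology.water_molecule_ids() if subset is None
                   else subset.members_per_frame[fi])
        for m in members:
            sites = topology.water_sites(int(m))
            total += 1
            for key in ("H1", "H2"):
                h = sites[key]
                if h in donating_h:
                    continue
                oh = minimum_image_displacements(
                    frame.positions[h] - frame.positions[sites["O"]],
                    frame.box_vectors)
                if oh @ normal / np.linalg.norm(oh) > cos_max:
                    counted += 1
                    break
    if total == 0:
        return 0.0
    return counted / total
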