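"""Canonical-ensemble Metropolis sampler for rigid 4-site water slabs.

This is the thermalizer behind ``build_slab_fixture(thermalize=True)``:
single-molecule translation/rotation moves of rigid TIP4P-Ew waters at a
target temperature, with site-site Coulomb plus O-O Lennard-Jones
interactions truncated molecule-wise at a spherical O-O cutoff, and
minimum-image periodicity.  An optional set of frozen external point
charges (the strand mimic) contributes Coulomb plus a soft excluded
volume on the water oxygens.

The sampler draws equilibrium configurations of the same 298 K canonical
ensemble that thermostatted dynamics would sample; "frames" taken every
fixed block of sweeps are treated downstream as the 1 ps analysis stride.
"""

from __future__ import annotations

import numpy as np

from .synthetic import WaterTemplate

KB = 0.0019872041        # kcal/(mol K)
COULOMB = 332.06371      # kcal*Angstrom/(mol e^2)


class WaterSlabSampler:
    """Metropolis Monte Carlo for rigid waters in a periodic slab box.

    Parameters
    ----------
    o_positions : (N, 3) oxygen positions, Angstrom.
    rotations : (N, 3, 3) rotation matrices (template local -> lab).
    box : (lx, ly, lz) orthorhombic box edges; vacuum along z.
    temperature : K.
    cutoff : molecule-based O-O cutoff, clamped to half the smallest
        in-plane box edge.
    translation_step, rotation_step_deg : maximum move amplitudes.
    external_positions/charges : frozen point-charge sites (e.g. the
        strand mimic); they interact with all water sites by Coulomb and
        with water oxygens by a soft LJ excluded volume.
    """

    def __init__(self, o_positions: np.ndarray, rotations: np.ndarray,
                 box: tuple[float, float, float],
                 template: WaterTemplate | None = None,
                 temperature: float = 298.0, cutoff: float = 9.0,
                 translation_step: float = 0.22,
                 rotation_step_deg: float = 25.0,
                 external_positions: np.ndarray | None = None,
                 external_charges: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.template = template or WaterTemplate.tip4pew()
        self.o_pos = np.array(o_positions, dtype=float)
        self.rot = np.array(rotations, dtype=float)
        self.n = self.o_pos.shape[0]
        self.box = np.asarray(box, dtype=float)
        self.kT = KB * temperature
        self.rc = min(cutoff, 0.5 * min(box[0], box[1]))
        self.dt = translation_step
        self.dr = np.deg2rad(rotation_step_deg)
        self.rng = rng or np.random.default_rng(0)

        self.local = self.template.local_coordinates()        # (4,3)
        self.q = self.template.charge_array()                 # (4,)
        lj = _load_lj(self.template)
        self.sigma, self.eps = lj
        self.qq = COULOMB * np.outer(self.q, self.q)          # (4,4)

        if external_positions is not None:
            self.ext_pos = np.asarray(external_positions, float)
            self.ext_q = np.asarray(external_charges, float)
            # soft excluded volume so waters cannot collapse onto bare charges
            self.ext_sigma, self.ext_eps = 3.1, 0.12
        else:
            self.ext_pos = None
            self.ext_q = None

        self.sites = self._all_sites()
        self.accepted = 0
        self.attempted = 0

    # -- geometry -------------------------------------------------------
    def _all_sites(self) -> np.ndarray:
        return self.o_pos[:, None, :] + np.einsum(
            "nij,sj->nsi", self.rot, self.local)

    def site_positions(self) -> np.ndarray:
        """(N, n_sites, 3) lab-frame site positions."""
        return self.sites

    # -- energies -------------------------------------------------------
    def _mol_energy(self, i: int, o_i: np.ndarray, s_i: np.ndarray) -> float:
        """Interaction energy of molecule i (at trial position) with the rest."""
        d = self.o_pos - o_i
        shift = -self.box * np.round(d / self.box)
        d_min = d + shift
        r2 = np.einsum("ij,ij->i", d_min, d_min)
        mask = r2 < self.rc ** 2
        mask[i] = False
        idx = np.flatnonzero(mask)
        e = 0.0
        if idx.size:
            s_j = self.sites[idx] + shift[idx][:, None, :]      # (m,4,3)
            diff = s_j[:, :, None, :] - s_i[None, None, :, :]   # (m,4_j,4_i,3)
            r = np.sqrt(np.einsum("mabx,mabx->mab", diff, diff))
            e += float(np.sum(self.qq[None, :, :] / r))
            r_oo = r[:, 0, 0]
            x6 = (self.sigma ** 2 / r_oo ** 2) ** 3
            e += float(np.sum(4.0 * self.eps * (x6 * x6 - x6)))
        if self.ext_pos is not None:
            d_ext = self.ext_pos[:, None, :] - s_i[None, :, :]
            d_ext -= self.box * np.round(d_ext / self.box)
            r = np.sqrt(np.einsum("eax,eax->ea", d_ext, d_ext))
            e += COULOMB * float(np.sum(self.ext_q[:, None] * self.q[None, :] / r))
            r_o = r[:, 0]
            x6 = (self.ext_sigma ** 2 / r_o ** 2) ** 3
            e += float(np.sum(4.0 * self.ext_eps * (x6 * x6 - x6)))
        return e

    def total_energy(self) -> float:
        """Total potential energy (kcal/mol); pairwise terms counted once."""
        e_pair = 0.5 * sum(
            self._mol_energy_pair_only(i) for i in range(self.n))
        e_ext = 0.0
        if self.ext_pos is not None:
            for i in range(self.n):
                e_ext += self._ext_energy(self.sites[i])
        return e_pair + e_ext

    def _mol_energy_pair_only(self, i: int) -> float:
        saved, self.ext_pos = self.ext_pos, None
        try:
            return self._mol_energy(i, self.o_pos[i], self.sites[i])
        finally:
            self.ext_pos = saved

    def _ext_energy(self, s_i: np.ndarray) -> float:
        d_ext = self.ext_pos[:, None, :] - s_i[None, :, :]
        d_ext -= self.box * np.round(d_ext / self.box)
        r = np.sqrt(np.einsum("eax,eax->ea", d_ext, d_ext))
        e = COULOMB * float(np.sum(self.ext_q[:, None] * self.q[None, :] / r))
        r_o = r[:, 0]
        x6 = (self.ext_sigma ** 2 / r_o ** 2) ** 3
        return e + float(np.sum(4.0 * self.ext_eps * (x6 * x6 - x6)))

    # -- moves ----------------------------------------------------------
    def _rotation_matrix(self, axis: np.ndarray, angle: float) -> np.ndarray:
        axis = axis / np.linalg.norm(axis)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return (np.eye(3) + np.sin(angle) * k
                + (1 - np.cos(angle)) * (k @ k))

    def step(self) -> None:
        i = int(self.rng.integers(self.n))
        e_old = self._mol_energy(i, self.o_pos[i], self.sites[i])
        if self.rng.random() < 0.5:
            o_new = self.o_pos[i] + self.rng.uniform(-self.dt, self.dt, 3)
            rot_new = self.rot[i]
        else:
            o_new = self.o_pos[i]
            dR = self._rotation_matrix(self.rng.normal(size=3),
                                       self.rng.uniform(-self.dr, self.dr))
            rot_new = dR @ self.rot[i]
        s_new = o_new[None, :] + self.local @ rot_new.T
        e_new = self._mol_energy(i, o_new, s_new)
        self.attempted += 1
        if e_new - e_old <= 0 or self.rng.random() < np.exp(
                -(e_new - e_old) / self.kT):
            self.o_pos[i] = o_new
            self.rot[i] = rot_new
            self.sites[i] = s_new
            self.accepted += 1

    def run(self, n_sweeps: int) -> None:
        for _ in range(int(n_sweeps) * self.n):
            self.step()

    @property
    def acceptance_ratio(self) -> float:
        return self.accepted / max(self.attempted, 1)


def _load_lj(template: WaterTemplate):
    import json
    from importlib import resources
    with resources.files("chiralsfg.data").joinpath(
            "charges_tip4pew.json").open() as fh:
        tab = json.load(fh)["lennard_jones_O"]
    return tab["sigma"], tab["epsilon_kcal_mol"]


def water_pair_energy(sites_a: np.ndarray, sites_b: np.ndarray,
                      template: WaterTemplate | None = None) -> float:
    """Interaction energy (kcal/mol) of two waters in open boundary
    conditions; reference implementation for tests."""
    template = template or WaterTemplate.tip4pew()
    q = template.charge_array()
    sigma, eps = _load_lj(template)
    e = 0.0
    for a in range(len(q)):
        for b in range(len(q)):
            r = float(np.linalg.norm(sites_b[b] - sites_a[a]))
            e += COULOMB * q[a] * q[b] / r
    r_oo = float(np.linalg.norm(sites_b[0] - sites_a[0]))
    x6 = (sigma / r_oo) ** 6
    return e + 4.0 * eps * (x6 * x6 - x6)
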