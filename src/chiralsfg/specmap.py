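"""Electric-field spectroscopic map: O-H bonds -> vibrational chromophores.

Each O-H bond of each water is converted into a chromophore by (i)
projecting the Coulomb electric field of all surrounding charged sites
(other molecules only, minimum image, spherical cutoff around the H)
onto the O->H unit vector, (ii) evaluating the map polynomials for the
10 transition frequency, position matrix element and dipole derivative,
and (iii) building lab-frame transition dipoles and axially symmetric
transition polarizability tensors along the bond.  The two O-H
chromophores of one molecule are then mixed by the intramolecular
coupling (a 2x2 vibrational exciton problem); intermolecular coupling is
deliberately absent so that spectra of disjoint molecule subsets add
exactly.

The map coefficients are configuration loaded from a data file; see
``chiralsfg/data/oh_stretch_map.txt`` for units and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .system import Frame, Topology, minimum_image_displacements

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class FieldSingularityError(RuntimeError):
    """A charged site (of another molecule) nearly coincides with an H atom."""


@dataclass
class MapCoefficients:
    """Polynomials and parameters of the electric-field map.

    ``freq_poly``/``dipole_poly`` are ascending-power polynomials in the
    projected field E (atomic units); ``position_matrix_poly`` is an
    ascending-power polynomial in the frequency (cm^-1) returning the
    position matrix element x10 in Angstrom.  ``coupling_params``
    (c0, c1) give the intramolecular coupling
    omega_12 = (c0 + c1*(E1+E2)) * x10(1) * x10(2).
    """

    freq_poly: np.ndarray
    dipole_poly: np.ndarray
    position_matrix_poly: np.ndarray
    coupling_params: np.ndarray
    polarizability_ratio: float
    field_cutoff: float
    isotope_mass_O: float
    mass_O16: float = 15.994915
    mass_H: float = 1.0078250319

    def __post_init__(self):
        for attr in ("freq_poly", "dipole_poly", "position_matrix_poly",
                     "coupling_params"):
            v = np.atleast_1d(np.asarray(getattr(self, attr), dtype=float))
            if v.size < 1:
                raise ValueError(f"{attr} needs at least one coefficient")
            setattr(self, attr, v)
        if self.field_cutoff <= 0:
            raise ValueError("field_cutoff must be positive")

    def isotope_frequency_factor(self) -> float:
        """sqrt(mu(16O-H)/mu(isotope O-H)): harmonic frequency ratio."""
        mu16 = self.mass_O16 * self.mass_H / (self.mass_O16 + self.mass_H)
        mu_iso = (self.isotope_mass_O * self.mass_H
                  / (self.isotope_mass_O + self.mass_H))
        return float(np.sqrt(mu16 / mu_iso))


def load_map_coefficients(path=None) -> MapCoefficients:
    """Load map coefficients from a key: values text file (default: the
    shipped parameterization)."""
    if path is None:
        src = resources.files("chiralsfg.data").joinpath("oh_stretch_map.txt")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        raw[key.strip()] = [float(tok) for tok in rest.split()]
    scalars = {k: raw[k][0] for k in ("polarizability_ratio", "field_cutoff",
                                      "isotope_mass_O", "mass_O16", "mass_H")}
    return MapCoefficients(freq_poly=raw["freq_poly"],
                           dipole_poly=raw["dipole_poly"],
                           position_matrix_poly=raw["position_matrix_poly"],
                           coupling_params=raw["coupling_params"],
                           **scalars)


@dataclass
class Chromophore:
    molecule_id: int
    bond_id: int          # 1 or 2
    omega: float          # cm^-1
    mu: np.ndarray        # lab-frame transition dipole (3,)
    alpha: np.ndarray     # lab-frame transition polarizability (3,3)
    position: np.ndarray  # H-atom position, Angstrom
    field: float = 0.0    # projected field, a.u.


@dataclass
class ExcitonPair:
    molecule_id: int
    omega_plus: float
    omega_minus: float
    mu_plus: np.ndarray
    mu_minus: np.ndarray
    alpha_plus: np.ndarray
    alpha_minus: np.ndarray

    @property
    def modes(self):
        return ((self.omega_minus, self.mu_minus, self.alpha_minus),
                (self.omega_plus, self.mu_plus, self.alpha_plus))


# ---------------------------------------------------------------------------
# Field evaluation
# ---------------------------------------------------------------------------

def field_projection(frame: Frame, topology: Topology, molecule_id: int,
                     bond_id: int, cutoff: float | None = None,
                     coeffs: MapCoefficients | None = None) -> float:
    """Electric field (a.u.) at the H atom projected on the O->H unit vector.

    Sums the Coulomb field of every charged site belonging to *other*
    molecules within ``cutoff`` (Angstrom, minimum image) of the H atom.
    """
    if cutoff is None:
        cutoff = (coeffs or load_map_coefficients()).field_cutoff
    sites = topology.water_sites(molecule_id)
    h_idx = sites["H1" if bond_id == 1 else "H2"]
    o_idx = sites["O"]
    e_vec, u = _field_at_h(frame, topology, o_idx, h_idx, cutoff)
    return float(e_vec @ u)


def _field_at_h(frame: Frame, topology: Topology, o_idx: int, h_idx: int,
                cutoff: float):
    pos = frame.positions
    box = frame.box_vectors
    d_oh = minimum_image_displacements(pos[h_idx] - pos[o_idx], box)
    u = d_oh / np.linalg.norm(d_oh)
    q = topology.partial_charge
    other = (topology.molecule_id != topology.molecule_id[h_idx]) & (q != 0.0)
    idx = np.flatnonzero(other)
    if idx.size == 0:
        return np.zeros(3), u
    disp = minimum_image_displacements(pos[h_idx] - pos[idx], box)  # site -> H
    r = np.linalg.norm(disp, axis=1)
    if np.any(r < 0.1):
        bad = idx[np.argmin(r)]
        raise FieldSingularityError(
            f"charged site {bad} within 0.1 A of H atom {h_idx} "
            f"(t={frame.time} ps)")
    sel = r < cutoff
    if not np.any(sel):
        return np.zeros(3), u
    disp_b = disp[sel] * BOHR_PER_ANGSTROM
    r_b = r[sel] * BOHR_PER_ANGSTROM
    e_vec = np.sum(q[idx[sel], None] * disp_b / r_b[:, None] ** 3, axis=0)
    return e_vec, u


# ---------------------------------------------------------------------------
# Map evaluation
# ---------------------------------------------------------------------------

def _polyval_ascending(coeffs: np.ndarray, x) -> np.ndarray:
    return np.polynomial.polynomial.polyval(x, coeffs)


def map_frequency(E, coeffs: MapCoefficients, isotope_scale: bool = False):
    """10 transition frequency (cm^-1) from the projected field."""
    omega = _polyval_ascending(coeffs.freq_poly, E)
    if isotope_scale:
        omega = omega * coeffs.isotope_frequency_factor()
    return omega


def map_transition_moments(E: float, bond_unit: np.ndarray,
                           coeffs: MapCoefficients,
                           omega: float | None = None):
    """Lab-frame transition dipole and polarizability for one O-H bond.

    mu = mu'(E) * x10(omega) * bond_unit; alpha is the axially symmetric
    bond tensor x10 * [ratio*I + (1-ratio) * u (x) u] (overall amplitude
    is arbitrary: only ratios of spectra are meaningful).
    """
    u = np.asarray(bond_unit, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-8:
        raise ValueError("bond_unit must be normalized")
    if omega is None:
        omega = float(_polyval_ascending(coeffs.freq_poly, E))
    x10 = float(_polyval_ascending(coeffs.position_matrix_poly, omega))
    mu_prime = float(_polyval_ascending(coeffs.dipole_poly, E))
    mu = mu_prime * x10 * u
    ratio = coeffs.polarizability_ratio
    alpha = x10 * (ratio * np.eye(3) + (1.0 - ratio) * np.outer(u, u))
    return mu, alpha


def intramolecular_coupling(E1: float, E2: float, x1: float, x2: float,
                            coeffs: MapCoefficients) -> float:
    c0, c1 = coeffs.coupling_params[:2]
    return float((c0 + c1 * (E1 + E2)) * x1 * x2)


def build_exciton_pair(ch1: Chromophore, ch2: Chromophore,
                       coeffs: MapCoefficients,
                       coupling: float | None = None) -> ExcitonPair:
    """Mix the two O-H chromophores of one molecule (2x2 eigenproblem).

    Eigenmode transition moments are the eigenvector-weighted sums of the
    bond moments; the Hamiltonian trace (omega1 + omega2) is conserved.
    """
    if ch1.molecule_id != ch2.molecule_id:
        raise ValueError("chromophores must belong to the same molecule")
    if coupling is None:
        x1 = float(_polyval_ascending(coeffs.position_matrix_poly, ch1.omega))
        x2 = float(_polyval_ascending(coeffs.position_matrix_poly, ch2.omega))
        coupling = intramolecular_coupling(ch1.field, ch2.field, x1, x2, coeffs)
    h = np.array([[ch1.omega, coupling], [coupling, ch2.omega]])
    evals, evecs = np.linalg.eigh(h)
    mus = np.stack([ch1.mu, ch2.mu])
    alphas = np.stack([ch1.alpha, ch2.alpha])
    mu_m = evecs[0, 0] * mus[0] + evecs[1, 0] * mus[1]
    mu_p = evecs[0, 1] * mus[0] + evecs[1, 1] * mus[1]
    al_m = evecs[0, 0] * alphas[0] + evecs[1, 0] * alphas[1]
    al_p = evecs[0, 1] * alphas[0] + evecs[1, 1] * alphas[1]
    return ExcitonPair(ch1.molecule_id, float(evals[1]), float(evals[0]),
                       mu_p, mu_m, al_p, al_m)


# ---------------------------------------------------------------------------
# Per-frame batch evaluation
# ---------------------------------------------------------------------------

def exciton_pairs_for_frame(frame: Frame, topology: Topology,
                            coeffs: MapCoefficients,
                            subset_molecules=None,
                            isotope_scale: bool = False) -> list[ExcitonPair]:
    """All exciton pairs for (a subset of) the waters of one frame."""
    mols = (np.asarray(sorted(subset_molecules), dtype=int)
            if subset_molecules is not None
            else topology.water_molecule_ids())
    pairs = []
    for mol in mols:
        sites = topology.water_sites(int(mol))
        chroms = []
        for bond_id, key in ((1, "H1"), (2, "H2")):
            h_idx, o_idx = sites[key], sites["O"]
            e_vec, u = _field_at_h(frame, topology, o_idx, h_idx,
                                   coeffs.field_cutoff)
            E = float(e_vec @ u)
            omega = float(map_frequency(E, coeffs, isotope_scale))
            mu, alpha = map_transition_moments(E, u, coeffs, omega=omega)
            chroms.append(Chromophore(int(mol), bond_id, omega, mu, alpha,
                                      frame.positions[h_idx].copy(), E))
        x1 = float(_polyval_ascending(coeffs.position_matrix_poly,
                                      chroms[0].omega))
        x2 = float(_polyval_ascending(coeffs.position_matrix_poly,
                                      chroms[1].omega))
        coup = intramolecular_coupling(chroms[0].field, chroms[1].field,
                                       x1, x2, coeffs)
        pairs.append(build_exciton_pair(chroms[0], chroms[1], coeffs,
                                        coupling=coup))
    return pairs
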