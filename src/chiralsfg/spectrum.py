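"""Second-order susceptibility spectra for water subsets.

The stick weight of one exciton eigenmode for tensor element (i, j, k)
-- (SFG, visible, IR) lab polarization indices, z = interface normal --
is alpha_ij * mu_k.  Sticks are broadened with a normalized complex line
shape in the inhomogeneous limit and averaged over frames; Im chi is the
reported observable (phase-resolved convention), Re chi is retained.
chi2_zyx is the chiral element (psp), chi2_yyz the achiral one (ssp).
Because intermolecular coupling is absent by construction, the spectrum
of a union of disjoint subsets is exactly the sum of the subset spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import wofz

from .specmap import MapCoefficients, exciton_pairs_for_frame, load_map_coefficients
from .system import Frame, Subset, Topology

ELEMENT_INDICES = {"zyx": (2, 1, 0), "yyz": (1, 1, 2)}

DEFAULT_GRID = np.arange(2800.0, 4000.0 + 0.5, 1.0)


@dataclass
class SpectrumResult:
    frequency_grid: np.ndarray
    chi_values: np.ndarray              # complex
    tensor_element: str
    subset_name: str
    n_frames: int
    mean_subset_size: float
    per_water: bool = False

    def __post_init__(self):
        grid = np.asarray(self.frequency_grid, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.chi_values)):
            raise ValueError("chi must be finite everywhere")
        self.frequency_grid = grid
        self.chi_values = np.asarray(self.chi_values, dtype=complex)

    @property
    def im(self) -> np.ndarray:
        return self.chi_values.imag


def frame_sticks(frame: Frame, topology: Topology, subset_members,
                 element: str, coeffs: MapCoefficients | None = None,
                 isotope_scale: bool = False) -> list[tuple[float, float]]:
    """(omega, weight) pairs for all exciton eigenmodes of subset waters."""
    if element not in ELEMENT_INDICES:
        raise ValueError(f"unknown tensor element {element!r}")
    i, j, k = ELEMENT_INDICES[element]
    coeffs = coeffs or load_map_coefficients()
    sticks = []
    pairs = exciton_pairs_for_frame(frame, topology, coeffs,
                                    subset_molecules=subset_members,
                                    isotope_scale=isotope_scale)
    for pair in pairs:
        for omega, mu, alpha in pair.modes:
            sticks.append((omega, float(alpha[i, j] * mu[k])))
    return sticks


def _lineshape_kernel(grid: np.ndarray, omega0: float, lineshape: str,
                      width: float) -> np.ndarray:
    """Normalized complex kernel whose imaginary part is the absorptive
    (unit-area) line shape and real part the dispersive counterpart."""
    delta = grid - omega0
    if lineshape == "lorentzian":
        return (1.0 / np.pi) / (-delta - 1j * width)
    if lineshape == "gaussian":
        z = (delta + 0j) / (width * np.sqrt(2.0))
        return 1j * wofz(z) / (width * np.sqrt(2.0 * np.pi))
    raise ValueError(f"unknown lineshape {lineshape!r}")


def accumulate_spectrum(frames, topology: Topology, subset: Subset | None,
                        element: str = "zyx",
                        grid: np.ndarray | None = None,
                        lineshape: str = "lorentzian", width: float = 5.0,
                        coeffs: MapCoefficients | None = None,
                        isotope_scale: bool = False) -> SpectrumResult:
    """Frame-averaged chi2 spectrum of a water subset.

    ``subset=None`` means all waters in every frame.  The imaginary part
    of the returned complex spectrum is the reported observable.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")
    grid = DEFAULT_GRID.copy() if grid is None else np.asarray(grid, float)
    coeffs = coeffs or load_map_coefficients()
    all_waters = set(int(m) for m in topology.water_molecule_ids())
    chi = np.zeros_like(grid, dtype=complex)
    sizes = []
    name = subset.name if subset is not None else "all"
    for fi, frame in enumerate(frames):
        if subset is None:
            members = all_waters
        else:
            members = subset.members_per_frame[fi]
        sizes.append(len(members))
        for omega0, w in frame_sticks(frame, topology, members, element,
                                      coeffs, isotope_scale):
            chi += w * _lineshape_kernel(grid, omega0, lineshape, width)
    chi /= len(frames)
    return SpectrumResult(grid, chi, element, name, len(frames),
                          float(np.mean(sizes)))


def normalize_per_water(result: SpectrumResult) -> SpectrumResult:
    """Divide by the mean subset size (the 'per water molecule' spectrum).

    Note this is mean-spectrum / mean-size; with a fluctuating subset it
    differs from averaging per-frame per-water spectra.
    """
    if result.mean_subset_size <= 0:
        raise ValueError("cannot normalize an empty subset")
    return replace(result,
                   chi_values=result.chi_values / result.mean_subset_size,
                   per_water=True)


def band_area(result: SpectrumResult, lo: float, hi: float,
              mode: str = "signed") -> float:
    """Trapezoidal integral of Im chi (signed) or |Im chi| over [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    grid = result.frequency_grid
    if lo < grid[0] or hi > grid[-1]:
        raise ValueError("band outside frequency grid")
    sel = (grid >= lo) & (grid <= hi)
    y = result.im[sel]
    if mode == "absolute":
        y = np.abs(y)
    elif mode != "signed":
        raise ValueError("mode must be 'signed' or 'absolute'")
    return float(np.trapezoid(y, grid[sel]))


def region_significance(result: SpectrumResult,
                        signal_band: tuple[float, float],
                        baseline_band: tuple[float, float]) -> float:
    """Two-sided two-sample t-test p-value: Im chi in signal vs baseline band."""
    grid = result.frequency_grid
    lo_s, hi_s = signal_band
    lo_b, hi_b = baseline_band
    if max(lo_s, lo_b) < min(hi_s, hi_b):
        raise ValueError("signal and baseline bands overlap")
    for lo, hi in (signal_band, baseline_band):
        if lo < grid[0] or hi > grid[-1]:
            raise ValueError("band outside frequency grid")
    a = result.im[(grid >= lo_s) & (grid <= hi_s)]
    b = result.im[(grid >= lo_b) & (grid <= hi_b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each band needs at least 2 grid points")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0  # identical constants: no evidence of a difference
    return float(stats.ttest_ind(a, b).pvalue)
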