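import numpy as np
import pytest

from chiralsfg.specmap import load_map_coefficients
from chiralsfg import synthetic as syn
from chiralsfg.system import Frame, Topology, orthorhombic_box


@pytest.fixture(scope="session")
def coeffs():
    return load_map_coefficients()


@pytest.fixture(scope="session")
def helix():
    """12-water right-handed chiral helix."""
    return syn.build_chiral_water_helix(12, handedness=1)


@pytest.fixture(scope="session")
def template_system():
    """Strand mimic over ~40 waters, 3 static frames (distinct seeds merged
    into a per-frame-varying trajectory)."""
    strand = syn.TemplateStrand(n_residues=5)
    topo, frames0 = syn.build_template_system(strand, n_waters=40, seed=7,
                                              n_frames=1)
    frames = list(frames0)
    for s in (8, 9):
        _, fr = syn.build_template_system(strand, n_waters=40, seed=s,
                                          n_frames=1)
        frames.append(fr[0])
    return topo, frames


@pytest.fixture
def single_water_system():
    """One template water with both O-H bonds in the xz plane."""
    template = syn.WaterTemplate.tip4pew()
    pos = syn.make_water(np.array([10.0, 10.0, 10.0]), np.eye(3), template)
    topo = syn.water_topology(1, template)
    frame = Frame(pos, orthorhombic_box(20, 20, 20))
    return topo, frame


def make_point_topology(n, charges=None, water=False):
    """Bare point-particle topology for geometry-level tests."""
    q = np.zeros(n) if charges is None else np.asarray(charges, float)
    return Topology(
        atom_name=np.array([f"X{i}" for i in range(n)]),
        residue_name=np.array(["ION"] * n),
        residue_index=np.arange(n),
        element=np.array(["C"] * n),
        partial_charge=q,
        molecule_id=np.arange(n),
        is_water=np.zeros(n, dtype=bool),
        water_site_role=np.array(["n/a"] * n, dtype=object),
    )
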