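"""Reading topologies/trajectories (via MDAnalysis) and tabular output.

Supported inputs: PDB or GRO topologies with DCD, XTC or multi-model PDB
trajectories.  Since coordinate formats carry no partial charges, a
charge table (JSON: residue name -> {atom name: charge}) or one of the
shipped force-field tables supplies them.  Water molecules are detected
by residue name and site roles by atom-name patterns, both overridable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np

from .system import Frame, Topology, ROLE_O, ROLE_H1, ROLE_H2, ROLE_VIRTUAL, ROLE_NA
from .spectrum import SpectrumResult


class FormatError(ValueError):
    """Unreadable or unsupported input file."""


class ChargesRequiredError(ValueError):
    """Topology carries no charges and no charge table covers an atom."""


DEFAULT_WATER_RESIDUES = {"HOH", "WAT", "TIP4", "TIP4P", "SOL", "T4E", "TP4E"}
_VIRTUAL_NAMES = {"MW", "M", "EPW", "EP", "DUM", "MW1"}


@dataclass
class ReadConfig:
    water_residues: set = dc_field(default_factory=lambda: set(DEFAULT_WATER_RESIDUES))
    charge_table: str | Path | None = None   # path, or the name "tip4pew"
    vacuum_axis: str = "z"


def _water_role(atom_name: str, h_seen: int) -> str:
    name = atom_name.strip().upper()
    if name in _VIRTUAL_NAMES:
        return ROLE_VIRTUAL
    if name.startswith("O"):
        return ROLE_O
    if name.startswith("H") or name.startswith(("1H", "2H")):
        return ROLE_H1 if h_seen == 0 else ROLE_H2
    return ROLE_NA


def _load_charge_table(spec_name) -> dict:
    if spec_name is None:
        return {}
    if str(spec_name) == "tip4pew":
        with resources.files("chiralsfg.data").joinpath(
                "charges_tip4pew.json").open() as fh:
            charges = json.load(fh)["charges"]
        role_names = {"O": ["OW", "O"], "H1": ["HW1", "H1"],
                      "H2": ["HW2", "H2"], "virtual": ["MW", "M", "EPW"]}
        table: dict = {}
        for res in DEFAULT_WATER_RESIDUES:
            table[res] = {}
            for role, names in role_names.items():
                for nm in names:
                    table[res][nm] = charges[role]
        return table
    with open(spec_name) as fh:
        return json.load(fh)


def read_system(topology_path, trajectory_path=None,
                config: ReadConfig | None = None) -> tuple[Topology, list[Frame]]:
    """Read a topology + trajectory into (Topology, list of Frames).

    Frames are returned in file order with populated box vectors; water
    detection follows the residue/atom-name rules in ``config``.
    """
    import MDAnalysis as mda

    config = config or ReadConfig()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is not None:
                u = mda.Universe(str(topology_path), str(trajectory_path))
            else:
                u = mda.Universe(str(topology_path))
    except Exception as exc:
        raise FormatError(
            f"cannot read {topology_path} / {trajectory_path}: {exc}") from exc

    n = len(u.atoms)
    resnames = np.array([a.resname.strip() for a in u.atoms])
    atnames = np.array([a.name.strip() for a in u.atoms])
    resids = np.array([a.resid for a in u.atoms])
    try:
        elements = np.array([a.element for a in u.atoms])
    except Exception:
        elements = np.array([nm[0] if nm else "" for nm in atnames])

    is_water = np.array([rn.upper() in config.water_residues for rn in resnames])
    roles = np.array([ROLE_NA] * n, dtype=object)
    # per-residue grouping defines molecules
    mol_id = np.zeros(n, dtype=int)
    key_to_mol: dict[tuple, int] = {}
    for i in range(n):
        key = (resnames[i], int(resids[i]), int(u.atoms[i].segindex))
        mol_id[i] = key_to_mol.setdefault(key, len(key_to_mol))
    for m in np.unique(mol_id[is_water]):
        idx = np.flatnonzero(mol_id == m)
        h_seen = 0
        for i in idx:
            roles[i] = _water_role(atnames[i], h_seen)
            if roles[i] in (ROLE_H1, ROLE_H2):
                h_seen += 1

    table = _load_charge_table(config.charge_table)
    charges = np.full(n, np.nan)
    if hasattr(u.atoms, "charges"):
        try:
            charges = np.asarray(u.atoms.charges, dtype=float)
        except Exception:
            pass
    for i in range(n):
        if np.isnan(charges[i]) or (config.charge_table is not None):
            entry = table.get(resnames[i].upper(), table.get(resnames[i], {}))
            if atnames[i] in entry:
                charges[i] = entry[atnames[i]]
    if np.any(np.isnan(charges)):
        missing = sorted({(str(resnames[i]), str(atnames[i]))
                          for i in np.flatnonzero(np.isnan(charges))})
        raise ChargesRequiredError(
            "charges required: topology carries none and the charge table "
            f"does not cover {missing[:5]}{'...' if len(missing) > 5 else ''}")

    topo = Topology(atom_name=atnames, residue_name=resnames,
                    residue_index=resids, element=elements,
                    partial_charge=charges, molecule_id=mol_id,
                    is_water=is_water, water_site_role=np.array(roles, dtype=object))

    frames = []
    for ts in u.trajectory:
        if ts.dimensions is None or not np.any(ts.dimensions[:3]):
            raise FormatError(f"frame {ts.frame} has no box vectors")
        box = mda.lib.mdamath.triclinic_vectors(ts.dimensions)
        frames.append(Frame(ts.positions.astype(float).copy(), np.asarray(box),
                            config.vacuum_axis, float(ts.time)))
    return topo, frames


def write_system(topology: Topology, frames: list[Frame], basename,
                 trajectory_format: str = "dcd") -> dict[str, str]:
    """Write PDB topology + trajectory + charge-table sidecar.

    Returns the mapping of artifact kind to path.  The sidecar JSON lets
    ``read_system`` restore partial charges exactly.
    """
    import MDAnalysis as mda

    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    n = topology.n_atoms
    u = mda.Universe.empty(n, n_residues=len(np.unique(topology.molecule_id)),
                           atom_resindex=_dense(topology.molecule_id),
                           trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in topology.atom_name])
    res_names = []
    seen = {}
    for i in range(n):
        m = int(topology.molecule_id[i])
        if m not in seen:
            seen[m] = str(topology.residue_name[i])
            res_names.append(seen[m])
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", list(range(1, len(res_names) + 1)))
    f0 = frames[0]
    u.atoms.positions = f0.positions
    u.dimensions = mda.lib.mdamath.triclinic_box(*f0.box_vectors)

    pdb_path = base.with_suffix(".pdb")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))
        traj_path = base.with_suffix("." + trajectory_format)
        with mda.Writer(str(traj_path), n) as w:
            for fr in frames:
                u.atoms.positions = fr.positions
                u.dimensions = mda.lib.mdamath.triclinic_box(*fr.box_vectors)
                w.write(u.atoms)

    table: dict[str, dict[str, float]] = {}
    for i in range(n):
        table.setdefault(str(topology.residue_name[i]), {})[
            str(topology.atom_name[i])] = float(topology.partial_charge[i])
    charge_path = base.parent / (base.name + ".charges.json")
    charge_path.write_text(json.dumps(table, indent=1))
    return {"topology": str(pdb_path), "trajectory": str(traj_path),
            "charges": str(charge_path)}


def _dense(ids: np.ndarray) -> np.ndarray:
    _, inv = np.unique(ids, return_inverse=True)
    order = {}
    out = np.empty(len(ids), dtype=int)
    for i, m in enumerate(ids):
        out[i] = order.setdefault(int(m), len(order))
    return out


# ---------------------------------------------------------------------------
# Spectrum tables
# ---------------------------------------------------------------------------

def write_spectrum_table(result: SpectrumResult, path) -> None:
    """TSV with columns frequency_cm1, re_chi, im_chi, subset.

    Floats are written with repr precision so a read round-trips
    bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["frequency_cm1\tre_chi\tim_chi\tsubset"]
    if len(result.frequency_grid) == 0:
        warnings.warn("writing an empty spectrum (header only)")
    for w, c in zip(result.frequency_grid, result.chi_values):
        lines.append(f"{float(w)!r}\t{float(c.real)!r}\t{float(c.imag)!r}"
                     f"\t{result.subset_name}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_table(path, tensor_element: str = "zyx") -> SpectrumResult:
    path = Path(path)
    freqs, chis, name = [], [], "all"
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("frequency_cm1"):
            raise FormatError(f"{path}: unexpected header {header!r}")
        for line in fh:
            w, re_c, im_c, name = line.rstrip("\n").split("\t")
            freqs.append(float(w))
            chis.append(complex(float(re_c), float(im_c)))
    return SpectrumResult(np.asarray(freqs), np.asarray(chis), tensor_element,
                          name, n_frames=0, mean_subset_size=0.0)
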