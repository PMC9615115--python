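"""Full-analysis orchestration: shells, subset spectra, diagnostics.

``run_full_analysis`` consumes one :class:`RunConfig`, runs every stage
of the dissection (all-water / first- / second-shell spectra, the
H-bond-taxonomy subset spectra in absolute and per-water form, shell
membership tables, H-bond count summaries, retention times, the
interfacial dipole grid and its annulus profile) and writes TSV/JSON
outputs plus a manifest stamped with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import ReadConfig, read_system, write_spectrum_table
from .shells import (HBondCriteria, ShellAssignment, assign_shells,
                     classify_first_shell, detect_hbonds, default_site_rules,
                     split_backbone_sidechain, voronoi_neighbors)
from .specmap import load_map_coefficients
from .spectrum import accumulate_spectrum, band_area, normalize_per_water
from .system import Frame, Subset, Topology
from .wateranalysis import (annulus_dipole_profile, dipole_grid,
                            mean_hbonds_per_water, retention_times,
                            signal_vs_retention)

log = logging.getLogger("chiralsfg")

TAXONOMY = ["hb_to_CO", "hb_to_NH", "hb_to_NH3", "strong_hb_CO",
            "backbone_region", "sidechain_region",
            "backbone_no_hb", "sidechain_no_hb"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    output_dir: str = "results/run"
    topology_path: str | None = None
    trajectory_path: str | None = None
    charge_table: str | None = None
    preset: str | None = None              # 'helix' | 'slab' | 'template'
    preset_params: dict = field(default_factory=dict)
    map_file: str | None = None
    element: str = "zyx"
    grid: tuple[float, float, float] = (2800.0, 4000.0, 1.0)
    lineshape: str = "lorentzian"
    width: float = 5.0
    hbond: dict = field(default_factory=dict)
    dipole_resolution: float = 1.0
    depth_range: tuple[float, float] = (0.0, 14.0)
    retention_time_step: float = 1.0
    spectrum_stride: int = 1
    analysis_stride: int = 1
    seed: int = 0
    vacuum_axis: str = "z"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.preset is None and self.topology_path is None:
            raise ValueError("config needs either input paths or a preset")
        for p in (self.topology_path, self.trajectory_path, self.map_file,
                  self.charge_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("grid", "depth_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def load_inputs(config: RunConfig) -> tuple[Topology, list[Frame]]:
    if config.preset is not None:
        from . import synthetic
        params = dict(config.preset_params)
        if config.preset == "helix":
            topo, frame = synthetic.build_chiral_water_helix(**params)
            return topo, [frame]
        params.setdefault("seed", config.seed)
        if config.preset == "slab":
            return synthetic.build_slab_fixture(**params)
        if config.preset == "template":
            return synthetic.build_template_system(**params)
        raise ValueError(f"unknown preset {config.preset!r}")
    rc = ReadConfig(charge_table=config.charge_table,
                    vacuum_axis=config.vacuum_axis)
    return read_system(config.topology_path, config.trajectory_path, rc)


def compute_shell_subsets(frames: list[Frame], topology: Topology,
                          criteria: HBondCriteria) -> dict[str, Subset]:
    """Per-frame Voronoi shells + H-bond taxonomy as named Subsets."""
    rules = default_site_rules(topology)
    all_ids = set(int(m) for m in topology.water_molecule_ids())
    names = ["all", "first_shell", "second_shell", "rest"] + TAXONOMY
    subsets = {n: Subset(n, []) for n in names}
    for frame in frames:
        nb = voronoi_neighbors(frame, topology)
        first, second = assign_shells(nb, topology)
        bb, sc = split_backbone_sidechain(first, nb, topology)
        hbonds = detect_hbonds(frame, topology, criteria, rules)
        asn = classify_first_shell(first, hbonds, bb, sc, topology, criteria,
                                   second_shell=second)
        subsets["all"].members_per_frame.append(set(all_ids))
        subsets["first_shell"].members_per_frame.append(set(first))
        subsets["second_shell"].members_per_frame.append(set(second))
        subsets["rest"].members_per_frame.append(all_ids - first - second)
        for key in TAXONOMY:
            subsets[key].members_per_frame.append(set(getattr(asn, key)))
    return subsets


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "seed": config.seed,
                      "version": __version__, "outputs": {}, "failed_stage": None}
    coeffs = load_map_coefficients(config.map_file)
    criteria = HBondCriteria(**config.hbond)
    lo, hi, step = config.grid
    grid = np.arange(lo, hi + step / 2, step)

    def table(df: pd.DataFrame, name: str) -> str:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            df.to_csv(fh, sep="\t", index=False)
        return str(path)

    stage = "load_inputs"
    try:
        topology, frames = load_inputs(config)
        spec_frames = frames[::config.spectrum_stride]
        ana_frames = frames[::config.analysis_stride]

        stage = "shells"
        t0 = _time.time()
        subsets = compute_shell_subsets(ana_frames, topology, criteria)
        log.info("shells: %d frames in %.1fs", len(ana_frames), _time.time() - t0)
        rows = []
        for name, sub in subsets.items():
            for fi, members in enumerate(sub.members_per_frame):
                rows += [{"frame": fi, "molecule_id": m, "label": name}
                         for m in sorted(members)]
        manifest["outputs"]["membership"] = table(pd.DataFrame(rows),
                                                  "membership.tsv")

        stage = "spectra"
        spec_subsets = compute_shell_subsets(spec_frames, topology, criteria) \
            if config.spectrum_stride != config.analysis_stride else subsets
        areas = {}
        pw_areas = {}
        for name, sub in spec_subsets.items():
            res = accumulate_spectrum(spec_frames, topology, sub,
                                      config.element, grid, config.lineshape,
                                      config.width, coeffs)
            path = outdir / f"spectrum_{name}.tsv"
            write_spectrum_table(res, path)
            manifest["outputs"][f"spectrum_{name}"] = str(path)
            areas[name] = band_area(res, lo, hi, mode="absolute")
            if name == "all":
                sig_lo, sig_hi = 2850.0, 3050.0
                base_lo, base_hi = 3800.0, 4000.0
                if grid[0] <= sig_lo and grid[-1] >= base_hi:
                    from .spectrum import region_significance
                    manifest["low_frequency_p_value"] = region_significance(
                        res, (sig_lo, sig_hi), (base_lo, base_hi))
            if res.mean_subset_size > 0:
                pw = normalize_per_water(res)
                pw_areas[name] = band_area(pw, lo, hi, mode="absolute")
                pw_path = outdir / f"spectrum_{name}_per_water.tsv"
                write_spectrum_table(pw, pw_path)
                manifest["outputs"][f"spectrum_{name}_per_water"] = str(pw_path)
        manifest["band_areas"] = areas
        if areas["all"] > 0:
            manifest["first_shell_area_fraction"] = areas["first_shell"] / areas["all"]

        stage = "hbond_summary"
        rows = []
        for name in ["all", "first_shell"] + TAXONOMY:
            sub = None if name == "all" else subsets[name]
            try:
                mean = mean_hbonds_per_water(ana_frames, topology, sub, criteria)
            except ValueError:
                mean = float("nan")
            rows.append({"subset": name, "mean_hbonds_per_water": mean,
                         "mean_size": (len(topology.water_molecule_ids())
                                       if sub is None else sub.mean_size())})
        manifest["outputs"]["hbond_summary"] = table(pd.DataFrame(rows),
                                                     "hbond_summary.tsv")

        stage = "retention"
        rows = []
        ret = {}
        for name in ["first_shell"] + TAXONOMY:
            sub = subsets[name]
            try:
                rec = retention_times(sub, config.retention_time_step)
            except ValueError:
                continue
            ret[name] = rec
            rows.append({"subset": name, "mean_retention_ps": rec.mean_retention,
                         "n_episodes": rec.n_episodes,
                         "n_censored": rec.n_censored})
        manifest["outputs"]["retention"] = table(pd.DataFrame(rows),
                                                 "retention.tsv")

        stage = "signal_vs_retention"
        rows = []
        for name, rec in ret.items():
            if name in pw_areas:
                rows.append({"subset": name,
                             "per_water_band_area": pw_areas[name],
                             "mean_retention_ps": rec.mean_retention})
        manifest["outputs"]["signal_vs_retention"] = table(
            pd.DataFrame(rows), "signal_vs_retention.tsv")

        stage = "dipole_grid"
        gridd = dipole_grid(ana_frames, topology, config.dipole_resolution,
                            config.depth_range)
        cx, cy = gridd.cell_centers()
        rows = []
        for i in range(len(cx)):
            for j in range(len(cy)):
                v = gridd.vectors[i, j]
                rows.append({"cell_x": cx[i], "cell_y": cy[j],
                             "vx": v[0], "vy": v[1], "vz": v[2],
                             "occupancy": int(gridd.occupancy[i, j])})
        manifest["outputs"]["dipole_grid"] = table(pd.DataFrame(rows),
                                                   "dipole_grid.tsv")
        center = (float(np.mean(cx)), float(np.mean(cy)))
        solute = topology.solute_atom_indices()
        if len(solute):
            p = frames[0].positions[solute]
            px, py = gridd.plane_axes
            center = (float(p[:, px].mean()), float(p[:, py].mean()))
        annuli = annulus_dipole_profile(gridd, center, config.dipole_resolution)
        manifest["outputs"]["annuli"] = table(annuli, "annuli.tsv")
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.error("stage %r failed; partial outputs retained in %s", stage, outdir)
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
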