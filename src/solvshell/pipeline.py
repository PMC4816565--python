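"""Configuration-driven orchestration of the analysis battery.

A :class:`RunConfig` names the inputs (or a synthetic preset), toggles
analyses (rmsd, rg, rmsf, rdf, gnow, hbonds, thermo) and sets windows
and criteria.  :func:`run` validates everything up front, executes each
enabled analysis, writes one TSV per analysis plus a JSON manifest
(package version, seed, parameters, input checksums) and returns the
paths.  Runs are deterministic: the same config and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import __version__
from .errors import ValidationError
from .hbonds import HBondCriteria, census
from .metrics import rg_series, rmsd_series, rmsf_per_residue, select_calpha
from .solvation import default_shell_edges, g_now_profile, rdf_from_com
from .structure_io import (
    Structure,
    Trajectory,
    classify_species,
    load_species_rules,
    read_structure,
    read_trajectory,
)
from .synthetic import (
    SolvationProfileSpec,
    SpeciesDensity,
    TwoStateSpec,
    make_toy_protein,
    make_trajectory,
    simulate_fluorescence_curve,
    solvate_with_profile,
    MOLAR_TO_PER_A3,
    WATER_OXYGEN_DENSITY,
)
from .thermo import analyze_curves, read_fluorescence_csv

__all__ = ["RunConfig", "run", "load_config", "SYNTHETIC_PRESETS", "build_preset"]

ANALYSES = ("rmsd", "rg", "rmsf", "rdf", "gnow", "hbonds", "thermo")

#: Solvent compositions used by the shipped synthetic presets: water at
#: its pure-liquid oxygen density, DMF at 2 mol/L, trehalose at 0.5 mol/L.
SYNTHETIC_PRESETS = {
    "ternary_hydration": dict(
        water=(WATER_OXYGEN_DENSITY, 3.0),
        dmf=(2.0 * MOLAR_TO_PER_A3, 0.2),
        trehalose=(0.5 * MOLAR_TO_PER_A3, 0.0),
    ),
    "binary_exclusion": dict(
        water=(WATER_OXYGEN_DENSITY, 0.3),
        dmf=(2.0 * MOLAR_TO_PER_A3, 3.0),
        trehalose=(0.0, 1.0),
    ),
    "uniform_ternary": dict(
        water=(WATER_OXYGEN_DENSITY, 1.0),
        dmf=(2.0 * MOLAR_TO_PER_A3, 1.0),
        trehalose=(0.5 * MOLAR_TO_PER_A3, 1.0),
    ),
}

#: Frame-to-frame Gaussian jitter (Å) for synthetic solvated
#: trajectories: snapshots are meant to be far enough apart in time for
#: local solvent rearrangement, so shell occupancies decorrelate.
SYNTHETIC_JITTER_SIGMA = 1.0


@dataclass
class RunConfig:
    """Validated inputs + toggles for one pipeline run."""

    output_dir: str
    seed: int = 0
    analyses: list[str] = field(default_factory=list)
    structure_path: str | None = None
    trajectory_path: str | None = None
    species_rules_path: str | None = None
    fluorescence_csv: str | None = None
    synthetic_preset: str | None = None
    synthetic_frames: int = 20
    n_residues: int = 20
    f_n: float | None = None
    f_d: float | None = None
    temperature: float = 313.0
    window_last: float = 0.6
    shell_step: float = 0.5
    shell_max: float = 10.0
    rdf_bin: float = 0.5
    rdf_max: float = 15.0
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    dmf_carbon: str = "carbonyl"
    strict_species: bool = True

    def validate(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValidationError(f"unknown analyses: {sorted(unknown)}")
        structural = {"rmsd", "rg", "rmsf", "rdf", "gnow", "hbonds"} & set(self.analyses)
        if structural:
            has_input = self.structure_path is not None or self.synthetic_preset is not None
            if not has_input:
                raise ValidationError(
                    f"analyses {sorted(structural)} need a structure (or a "
                    "synthetic preset)"
                )
            if self.synthetic_preset is not None and self.synthetic_preset not in SYNTHETIC_PRESETS:
                raise ValidationError(
                    f"unknown synthetic preset {self.synthetic_preset!r}; "
                    f"one of {sorted(SYNTHETIC_PRESETS)}"
                )
        if "thermo" in self.analyses:
            if self.fluorescence_csv is None and self.synthetic_preset is None:
                raise ValidationError("thermo needs a fluorescence CSV (or a synthetic preset)")
            if self.fluorescence_csv is not None and (self.f_n is None or self.f_d is None):
                raise ValidationError("thermo on a CSV needs the F_N and F_D anchors")
        for path in (
            self.structure_path,
            self.trajectory_path,
            self.species_rules_path,
            self.fluorescence_csv,
        ):
            if path is not None and not os.path.exists(path):
                raise ValidationError(f"input not found: {path}")


def load_config(path: str) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config must be a YAML mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "output_dir" not in data:
        raise ValidationError("config must set output_dir")
    return RunConfig(**data)


def build_preset(
    preset: str, seed: int, n_frames: int = 20, n_residues: int = 20
) -> Trajectory:
    """Synthetic solvated trajectory for a named composition preset."""
    if preset not in SYNTHETIC_PRESETS:
        raise ValidationError(f"unknown preset {preset!r}")
    comp = SYNTHETIC_PRESETS[preset]
    protein = make_toy_protein(n_residues, "helix")
    spec = SolvationProfileSpec(
        water=SpeciesDensity(*comp["water"]),
        dmf=SpeciesDensity(*comp["dmf"]),
        trehalose=SpeciesDensity(*comp["trehalose"]),
        seed=seed,
    )
    system = solvate_with_profile(protein, spec)
    return make_trajectory(
        system, "jitter", n_frames=n_frames, seed=seed + 1, sigma=SYNTHETIC_JITTER_SIGMA
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def run(config: RunConfig) -> dict[str, Any]:
    """Execute every enabled analysis and write TSVs + manifest."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    traj: Trajectory | None = None
    species = None
    if {"rmsd", "rg", "rmsf", "rdf", "gnow", "hbonds"} & set(config.analyses):
        if config.structure_path is not None:
            structure = read_structure(config.structure_path)
            rules = (
                load_species_rules(config.species_rules_path)
                if config.species_rules_path
                else None
            )
            species = classify_species(
                structure,
                rules=rules,
                strict=config.strict_species,
                dmf_carbon=config.dmf_carbon,
            )
            if config.trajectory_path is not None:
                traj = read_trajectory(config.trajectory_path, structure)
            else:
                traj = Trajectory(structure, structure.coordinates[None, :, :])
        else:
            traj = build_preset(
                config.synthetic_preset,
                config.seed,
                n_frames=config.synthetic_frames,
                n_residues=config.n_residues,
            )
            species = classify_species(traj.parent, dmf_carbon=config.dmf_carbon)

    def out_path(name: str) -> str:
        return os.path.join(config.output_dir, name)

    if "rmsd" in config.analyses:
        calpha = select_calpha(traj.parent, species)
        series = rmsd_series(traj, calpha, units="nm")
        _write_tsv(series.to_frame(), out_path("rmsd.tsv"))
        outputs["rmsd"] = out_path("rmsd.tsv")
    if "rg" in config.analyses:
        prot = np.flatnonzero(species.species == "protein")
        series = rg_series(traj, prot, units="nm")
        _write_tsv(series.to_frame(), out_path("rg.tsv"))
        outputs["rg"] = out_path("rg.tsv")
    if "rmsf" in config.analyses:
        calpha = select_calpha(traj.parent, species)
        table = rmsf_per_residue(traj, calpha, last_fraction=config.window_last)
        df = table.to_frame()
        _write_tsv(df, out_path("rmsf.tsv"))
        outputs["rmsf"] = out_path("rmsf.tsv")
        outputs["total_rmsf_nm"] = table.total_rmsf
    if "rdf" in config.analyses:
        bins = np.arange(0.0, config.rdf_max + 1e-9, config.rdf_bin)
        for role in ("water_oxygen", "dmf_carbon", "trehalose_hydroxyl_oxygen"):
            attr = {"water_oxygen": "is_water_oxygen",
                    "dmf_carbon": "is_dmf_carbon",
                    "trehalose_hydroxyl_oxygen": "is_trehalose_hydroxyl_oxygen"}[role]
            if not np.any(getattr(species, attr)):
                continue
            res = rdf_from_com(traj, species, role, bins=bins, window_last=config.window_last)
            _write_tsv(res.to_frame(), out_path(f"rdf_{role}.tsv"))
            outputs[f"rdf_{role}"] = out_path(f"rdf_{role}.tsv")
    if "gnow" in config.analyses:
        shells = default_shell_edges(config.shell_step, config.shell_max)
        profile = g_now_profile(traj, species, shells=shells)
        _write_tsv(profile.to_frame(), out_path("gnow.tsv"))
        outputs["gnow"] = out_path("gnow.tsv")
    if "hbonds" in config.analyses:
        criteria = HBondCriteria(
            distance_cutoff=config.hbond_distance, angle_cutoff=config.hbond_angle
        )
        result = census(traj, species, criteria)
        _write_tsv(result.per_frame, out_path("hbonds_frames.tsv"))
        _write_tsv(result.summary(), out_path("hbonds_summary.tsv"))
        outputs["hbonds"] = out_path("hbonds_summary.tsv")
    if "thermo" in config.analyses:
        if config.fluorescence_csv is not None:
            curves = read_fluorescence_csv(
                config.fluorescence_csv,
                f_n=config.f_n,
                f_d=config.f_d,
                temperature=config.temperature,
            )
        else:
            curves = [
                simulate_fluorescence_curve(
                    TwoStateSpec(
                        delta_g0=5.0 + 2.0 * tre,
                        noise_sd=5.0,
                        trehalose_molar=tre,
                        seed=config.seed + i,
                    )
                )
                for i, tre in enumerate((0.0, 0.5, 1.0))
            ]
        results, comparison = analyze_curves(curves)
        rows = []
        for res in results:
            rows.append(
                {
                    "trehalose_M": res.trehalose_molar,
                    "slope_kJmol_per_pct": res.slope,
                    "intercept_kJmol": res.intercept,
                    "r_squared": res.r_squared,
                }
            )
        import pandas as pd

        _write_tsv(pd.DataFrame(rows), out_path("thermo_fits.tsv"))
        _write_tsv(comparison.reset_index(), out_path("thermo_comparison.tsv"))
        outputs["thermo"] = out_path("thermo_fits.tsv")

    manifest = {
        "solvshell_version": __version__,
        "seed": config.seed,
        "analyses": sorted(config.analyses),
        "parameters": {
            k: v
            for k, v in vars(config).items()
            if k not in {"output_dir"} and v is not None
        },
        "input_checksums": {
            path: _sha256(path)
            for path in (
                config.structure_path,
                config.trajectory_path,
                config.species_rules_path,
                config.fluorescence_csv,
            )
            if path is not None
        },
        "outputs": {k: v for k, v in outputs.items() if isinstance(v, str)},
    }
    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = manifest_path
    return outputs
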