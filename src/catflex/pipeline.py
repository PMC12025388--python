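"""End-to-end orchestration: filters → dedup → RMSD profiles → descriptors →
Boltzmann summary, over a directory of per-coordination-mode ensembles.

A dataset directory (as written by ``catflex generate`` or assembled by hand
from upstream output) contains:

    fragment_spec.yaml        atom-role assignment (shared by all groups)
    metadata.yaml             ligand id, anchor indices, chirality sign,
                              per-group file names
    <mode>.xyz                conformer ensemble, crest dialect (hartree)
    <mode>_baseline.xyz       the conformer-search input structure + energy
    <mode>_properties.csv     per-conformer electronic property table

All pipeline outputs are delimited text plus a JSON manifest, so every stage
is independently inspectable and a rerun with the same inputs and config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boltzmann import DEFAULT_TEMPERATURE_K, group_summary, pool_coordination_modes
from .complexes import ComplexTemplate, FragmentSpec
from .descriptors import descriptor_table
from .ensembles import (
    apply_retention_filters,
    deduplicate,
    energy_window_filter,
    relative_energies,
    summarize_ensemble,
)
from .rmsd import rmsd_profile
from .structures import (
    ConformerEnsemble,
    PropertyTable,
    ingest_property_table,
    read_ensemble_xyz,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_dataset"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Tunables of one pipeline run; round-trips through YAML."""

    data_dir: str = "."
    output_dir: str = "out"
    window_kcal: float = 6.0
    rmsd_tol: float = 0.25
    energy_tol_kj: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE_K
    sphere_radius: float = 3.5
    radii_scale: float = 1.17
    grid_spacing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_kcal", "rmsd_tol", "energy_tol_kj", "temperature",
                     "sphere_radius", "radii_scale", "grid_spacing"):
            if getattr(self, name) <= 0 and name != "window_kcal":
                raise ValueError(f"{name} must be positive")
        if self.window_kcal < 0:
            raise ValueError("window_kcal must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class DatasetGroup:
    """One coordination-mode conformer set plus its sidecar files."""

    template: ComplexTemplate
    ensemble: ConformerEnsemble
    table: PropertyTable


@dataclass
class Dataset:
    spec: FragmentSpec
    groups: list[DatasetGroup]
    anchor_indices: tuple[int, int, int] | None
    expected_chirality_sign: int | None
    ligand_id: str


def load_dataset(data_dir: str | Path) -> Dataset:
    """Read a dataset directory (see module docstring for the layout)."""
    root = Path(data_dir)
    meta_path = root / "metadata.yaml"
    if not meta_path.exists():
        raise PipelineError(f"load: missing {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    spec = FragmentSpec.from_yaml(root / "fragment_spec.yaml")
    anchors = tuple(meta["anchor_indices"]) if meta.get("anchor_indices") else None
    chir_sign = meta.get("expected_chirality_sign")
    chiral_ref = tuple(meta["chiral_reference"]) if meta.get("chiral_reference") else None
    groups: list[DatasetGroup] = []
    for g in meta["groups"]:
        mode = g["coordination_mode"]
        substrate_kind = "NBD" if mode == "nbd" else "S"
        xyz = root / g["xyz"]
        if not xyz.exists():
            raise PipelineError(f"load: missing ensemble file {xyz}")
        baseline = None
        if g.get("baseline_xyz"):
            base_ens = read_ensemble_xyz(root / g["baseline_xyz"], dialect="crest")
            baseline = base_ens.members[0]
        ensemble = read_ensemble_xyz(
            xyz,
            dialect="crest",
            ligand_id=meta.get("ligand_id", ""),
            substrate_kind=substrate_kind,
            coordination_mode=mode,
            baseline=baseline,
            stage="dft",
        )
        prop_path = root / g["properties"]
        if not prop_path.exists():
            raise PipelineError(
                f"descriptors: property table {prop_path} required but missing"
            )
        table = ingest_property_table(prop_path, ensemble)
        template = ComplexTemplate(
            ligand_id=meta.get("ligand_id", ""),
            substrate_kind=substrate_kind,
            coordination_mode=mode,
            chiral_reference=chiral_ref,
        )
        groups.append(DatasetGroup(template=template, ensemble=ensemble, table=table))
    return Dataset(
        spec=spec,
        groups=groups,
        anchor_indices=anchors,
        expected_chirality_sign=chir_sign,
        ligand_id=meta.get("ligand_id", ""),
    )


def _surviving_indices(filtered: ConformerEnsemble, original: ConformerEnsemble) -> list[int]:
    """Original member indices of the filtered ensemble, in filtered order
    (members are shared objects, so identity suffices)."""
    by_id = {id(m): i for i, m in enumerate(original.members)}
    return [by_id[id(m)] for m in filtered.members]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over a dataset directory and write the report bundle.

    Per group: retention filters (chirality + coordination-mode), energy
    window, deduplication, fragment-resolved RMSD profile, descriptor table.
    Pooled over groups: Boltzmann-weighted descriptor summary (major sets
    pooled, minor sets pooled, NBD separate) plus a per-set summary.

    Returns a dict of the output DataFrames; files land in
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(config.data_dir)

    summaries = []
    removal_rows = []
    pooled_desc = []
    pooled_energy = []
    pooled_modes = []
    results: dict = {}

    for grp in dataset.groups:
        mode = grp.template.coordination_mode
        original = grp.ensemble
        try:
            retained, log = apply_retention_filters(
                original,
                grp.template,
                dataset.spec,
                anchor_indices=dataset.anchor_indices,
                expected_chirality_sign=dataset.expected_chirality_sign,
            )
        except Exception as exc:
            raise PipelineError(f"retention[{mode}]: {exc}") from exc
        for r in log:
            removal_rows.append(
                {"coordination_mode": mode, "member": r.member_index,
                 "reason": r.reason, "detail": r.detail}
            )
        try:
            windowed = energy_window_filter(retained, config.window_kcal)
            distinct = deduplicate(windowed, config.rmsd_tol, config.energy_tol_kj)
        except Exception as exc:
            raise PipelineError(f"filter/dedup[{mode}]: {exc}") from exc

        idx = _surviving_indices(distinct, original)
        table = PropertyTable(frame=grp.table.frame.iloc[idx].reset_index(drop=True))

        try:
            profile = rmsd_profile(distinct, dataset.spec)
        except Exception as exc:
            raise PipelineError(f"rmsd[{mode}]: {exc}") from exc
        profile.insert(0, "original_member", idx)
        profile.to_csv(out / f"rmsd_profile_{mode}.csv", index=False)
        results[f"rmsd_profile_{mode}"] = profile

        try:
            desc = descriptor_table(
                distinct,
                dataset.spec,
                table,
                sphere_radius=config.sphere_radius,
                radii_scale=config.radii_scale,
                grid_spacing=config.grid_spacing,
            )
        except Exception as exc:
            raise PipelineError(f"descriptors[{mode}]: {exc}") from exc
        desc.insert(0, "original_member", idx)
        desc.to_csv(out / f"descriptors_{mode}.csv", index=False)
        results[f"descriptors_{mode}"] = desc

        summaries.append(summarize_ensemble(original, distinct, dataset.spec, log))
        pooled_desc.append(desc)
        pooled_energy.append(distinct.energies_in("kJ/mol"))
        pooled_modes.extend([mode] * len(distinct))

    summary_frame = pd.DataFrame(
        [
            {
                "ligand_id": s.ligand_id,
                "substrate_kind": s.substrate_kind,
                "coordination_mode": s.coordination_mode,
                "n_input": s.n_crest,
                "n_distinct": s.n_distinct_dft,
                "delta_e_min_kj": s.delta_e_range_kj[0],
                "delta_e_max_kj": s.delta_e_range_kj[1],
                "rmsd_ligand_min": s.rmsd_range_ligand[0],
                "rmsd_ligand_max": s.rmsd_range_ligand[1],
                "rmsd_substrate_min": s.rmsd_range_substrate[0],
                "rmsd_substrate_max": s.rmsd_range_substrate[1],
                "n_removed_chirality": s.n_removed_chirality,
                "n_removed_coordination": s.n_removed_coordination,
            }
            for s in summaries
        ]
    )
    summary_frame.to_csv(out / "summary.csv", index=False)
    results["summary"] = summary_frame

    pd.DataFrame(
        removal_rows, columns=["coordination_mode", "member", "reason", "detail"]
    ).to_csv(out / "removals.csv", index=False)

    all_desc = pd.concat(pooled_desc, ignore_index=True)
    all_energy = np.concatenate(pooled_energy) if pooled_energy else np.array([])
    desc_cols = ["vbur_metal", "vbur_donor", "q_metal", "q_donor", "gap_ev"]
    try:
        pooled = group_summary(
            all_desc, all_energy, pool_coordination_modes(pooled_modes),
            temperature=config.temperature, descriptor_columns=desc_cols,
        )
        by_set = group_summary(
            all_desc, all_energy, list(pooled_modes),
            temperature=config.temperature, descriptor_columns=desc_cols,
        )
    except Exception as exc:
        raise PipelineError(f"boltzmann: {exc}") from exc
    pooled.to_csv(out / "boltzmann_summary.csv", index=False)
    by_set.to_csv(out / "boltzmann_by_set.csv", index=False)
    results["boltzmann_summary"] = pooled
    results["boltzmann_by_set"] = by_set

    manifest = {
        "catflex_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_groups": len(dataset.groups),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
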