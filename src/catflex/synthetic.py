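"""Synthetic catalyst-complex ensembles with known ground truth.

Every pipeline stage needs realistic input without running quantum chemistry
or a conformer search, so this module builds a schematic Rh-bisphosphine
complex and samples conformer ensembles around it with the statistical
signature of the real systems:

* a rigid P-Rh-P core and rigid axial-chirality backbone (the real search
  constrains the aryl rings on the chiral axis, so these atoms barely move),
* flexible ligand arms (per-atom Gaussian displacements of several tenths of
  an Å up to ~1 Å, producing ligand-part RMSDs of a few Å),
* a rigid substrate (displacements of a few hundredths of an Å, keeping
  substrate-part RMSD well under 1 Å),
* right-skewed, minimum-anchored energy spreads (exponential ΔE, mean of
  order 10 kJ/mol, i.e. ensembles spanning tens of kJ/mol),
* per-conformer electronic properties drawn from a declared linear map of
  the true ligand distortion plus Gaussian noise, recorded in a truth
  record so recovery can be asserted exactly.

Each conformer is additionally given a random rigid motion, so downstream
RMSD code cannot pass by coordinate coincidence. A single integer seed
drives all randomness; independent streams are split per (seed, stream)
pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

import numpy as np

from .complexes import (
    ComplexTemplate,
    FragmentSpec,
    dihedral_angle,
)
from .structures import ConformerEnsemble, PropertyTable, Structure
from .units import HARTREE_TO_KJ_PER_MOL, HARTREE_TO_EV

import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SyntheticComplex",
    "make_complex_template",
    "make_ensemble",
    "make_dedup_fixture",
    "mirror_structure",
    "flip_substrate_quadrant",
    "random_rigid_motion",
    "write_dataset",
]

#: electronic-property model: name -> (base value, slope per Å of true
#: ligand distortion, Gaussian noise sd). Units: au for charges, eV for gap.
DEFAULT_DESCRIPTOR_MODEL: Mapping[str, tuple[float, float, float]] = {
    "q_metal": (-0.20, 0.02, 0.005),
    "q_donor": (1.00, -0.01, 0.003),
    "gap_ev": (3.30, 0.10, 0.05),
}

#: electronic energy origin of the synthetic complexes (hartree); the
#: absolute value is irrelevant (only differences enter the analysis) but a
#: realistic magnitude exercises the unit plumbing.
BASE_ENERGY_HARTREE = -2500.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Defaults emulate the reported phenomenology: rigid substrate
    (``sigma_substrate`` = 0.05 Å), flexible ligand (``sigma_ligand`` =
    0.8 Å), exponential energy spread with mean 10 kJ/mol, and a
    conformer-search baseline sitting 10 kJ/mol above the synthetic minimum
    so that relative energies take both signs.
    """

    n_ligand_atoms: int = 14  # includes the two P donors and 2 backbone atoms
    n_substrate_atoms: int = 8  # includes 2 anchor carbons and the reference O
    sigma_ligand: float = 0.8
    sigma_substrate: float = 0.05
    n_conformers: int = 30
    energy_scale_kj: float = 10.0
    baseline_offset_kj: float = 10.0
    n_wells: int = 5
    well_separation: float = 3.0
    well_energy_gap_kj: float = 3.0
    jitter: float = 0.02
    replicates_per_well: int | tuple[int, ...] = 4
    descriptor_model: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_MODEL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligand_atoms < 5:
            raise ValueError("need at least 5 ligand atoms (2 donors + chiral backbone + arm)")
        if self.n_substrate_atoms < 3:
            raise ValueError("need at least 3 substrate atoms (2 anchors + reference)")
        for name in ("sigma_ligand", "sigma_substrate", "energy_scale_kj", "jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class SyntheticComplex:
    """Base geometry plus everything the pipeline needs to analyse it."""

    structure: Structure
    spec: FragmentSpec
    template: ComplexTemplate
    anchor_indices: tuple[int, int, int]
    expected_chirality_sign: int

    #: indices displaced with sigma_ligand (flexible arms); the complement of
    #: the rigid core within the ligand
    flexible_ligand_indices: tuple[int, ...] = ()


_MODE_SIGNS = {  # (x-sign, y-sign) of the reference atom in the quadrant frame
    "major1": (1, 1),
    "major2": (-1, 1),
    "minor1": (1, -1),
    "minor2": (-1, -1),
    "nbd": (1, 1),  # placeholder; the classifier is not applied to NBD
}


def make_complex_template(
    config: GeneratorConfig,
    ligand_id: str = "L1",
    coordination_mode: str = "major1",
) -> SyntheticComplex:
    """Build a schematic but geometrically valid base complex.

    Layout (all deterministic): Rh at the origin; two P donors symmetric
    about the yz-plane below the substrate; two backbone atoms defining the
    axial-chirality dihedral; ligand arms growing outward from the backbone;
    substrate anchors above the donor plane with the directing-group oxygen
    placed in the quadrant that realizes the requested coordination mode.
    No two atoms are closer than 0.8 Å.
    """
    n_lig = config.n_ligand_atoms
    n_sub = config.n_substrate_atoms
    substrate_kind = "NBD" if coordination_mode == "nbd" else "S"

    symbols: list[str] = ["Rh"]
    coords: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]

    # donors (ligand indices 1, 2)
    symbols += ["P", "P"]
    coords += [(1.55, -1.40, 0.0), (-1.55, -1.40, 0.0)]
    # chiral backbone atoms (indices 3, 4); dihedral 3-1-2-4 is the axial
    # chirality marker and is kept rigid during ensemble sampling
    symbols += ["C", "C"]
    coords += [(2.30, -2.60, 0.55), (-2.30, -2.60, -0.55)]
    # flexible arms, alternating sides
    arm_indices = []
    for t in range(n_lig - 4):
        side = 1 if t % 2 == 0 else -1
        j = t // 2 + 1
        symbols.append("C")
        coords.append((side * (2.30 + 0.75 * j), -2.60 - 0.75 * j, side * 0.55))
        arm_indices.append(len(symbols) - 1)

    lig_first, lig_last = 1, n_lig
    # substrate: two anchor carbons, then the reference oxygen in the
    # requested quadrant (frame axes at the base geometry: x = (0,-1,0),
    # y = (1,0,0), z = (0,0,1)), then a carbon chain
    c1, c2 = len(symbols), len(symbols) + 1
    symbols += ["C", "C"]
    coords += [(0.70, 1.35, 0.75), (-0.70, 1.35, 0.75)]
    sx, sy = _MODE_SIGNS[coordination_mode]
    ref = len(symbols)
    symbols.append("O")
    coords.append((sy * 1.10, -sx * 0.80, 1.60))
    for k in range(n_sub - 3):
        symbols.append("C")
        coords.append((0.35 * (-1) ** k, 2.30 + 0.80 * k, 1.10))

    structure = Structure(
        symbols=symbols,
        coords=np.array(coords),
        label=f"{ligand_id}-Rh-{substrate_kind}-{coordination_mode}",
    )
    d = np.linalg.norm(
        structure.coords[:, None, :] - structure.coords[None, :, :], axis=-1
    )
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.8:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"infeasible atom counts: atoms {i} and {j} end up {d.min():.2f} Å apart"
        )

    spec = FragmentSpec(
        metal_index=0,
        donor_indices=(1, 2),
        ligand_indices=tuple(range(lig_first, lig_last + 1)),
        substrate_indices=tuple(range(lig_last + 1, len(symbols))),
    )
    spec.validate_for(structure)
    base_dihedral = dihedral_angle(
        structure.coords[3], structure.coords[1], structure.coords[2], structure.coords[4]
    )
    template = ComplexTemplate(
        ligand_id=ligand_id,
        substrate_kind=substrate_kind,
        coordination_mode=coordination_mode,
        chiral_reference=(3, 1, 2, 4),
    )
    return SyntheticComplex(
        structure=structure,
        spec=spec,
        template=template,
        anchor_indices=(c1, c2, ref),
        expected_chirality_sign=1 if base_dihedral > 0 else -1,
        flexible_ligand_indices=tuple(arm_indices),
    )


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random proper rotation (via normalized quaternion) and a
    translation drawn uniformly from [-5, 5]^3 Å."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-5.0, 5.0, size=3)
    return R, t


def _role_sigmas(complex_: SyntheticComplex, config: GeneratorConfig) -> np.ndarray:
    """Per-atom displacement scale: flexible arms get sigma_ligand, everything
    else (metal, donors, chiral backbone, substrate) the rigid sigma_substrate."""
    n = complex_.structure.n_atoms
    sig = np.full(n, config.sigma_substrate)
    sig[list(complex_.flexible_ligand_indices)] = config.sigma_ligand
    return sig


def make_ensemble(
    config: GeneratorConfig,
    complex_: SyntheticComplex,
    stream: int = 1,
) -> tuple[ConformerEnsemble, PropertyTable, dict]:
    """Sample a conformer ensemble, its property table and the truth record.

    Conformer i = base + per-atom Gaussian displacement (role-dependent
    scale) followed by a random rigid motion of the whole frame. Energies
    are E_min + Exp(mean = energy_scale_kj); the conformer-search baseline
    sits ``baseline_offset_kj`` above E_min. Electronic properties follow
    the declared linear model in the true ligand distortion.
    """
    rng = config.rng(stream)
    base = complex_.structure
    sig = _role_sigmas(complex_, config)
    lig_part = sorted(set(complex_.spec.ligand_indices) | {complex_.spec.metal_index})

    members: list[Structure] = []
    true_distortion = np.empty(config.n_conformers)
    delta_e = rng.exponential(config.energy_scale_kj, size=config.n_conformers)
    for i in range(config.n_conformers):
        disp = rng.normal(size=(base.n_atoms, 3)) * sig[:, None]
        # true ligand-part distortion: rms displacement over the part that
        # the descriptor model keys on (known exactly, pre rigid motion)
        true_distortion[i] = float(np.sqrt(np.mean(disp[lig_part] ** 2) * 3.0))
        R, t = random_rigid_motion(rng)
        coords = (base.coords + disp) @ R.T + t
        members.append(
            Structure(
                symbols=list(base.symbols),
                coords=coords,
                energy=BASE_ENERGY_HARTREE + delta_e[i] / HARTREE_TO_KJ_PER_MOL,
                energy_unit="hartree",
                label=f"{base.label}|conf{i}",
            )
        )

    baseline = Structure(
        symbols=list(base.symbols),
        coords=base.coords.copy(),
        energy=BASE_ENERGY_HARTREE + config.baseline_offset_kj / HARTREE_TO_KJ_PER_MOL,
        energy_unit="hartree",
        label=f"{base.label}|baseline",
    )
    ensemble = ConformerEnsemble(
        members=members,
        ligand_id=complex_.template.ligand_id,
        substrate_kind=complex_.template.substrate_kind,
        coordination_mode=complex_.template.coordination_mode,
        baseline=baseline,
        stage="dft",
    )

    # electronic-property model
    model = config.descriptor_model
    truth: dict = {
        "delta_e_kj": delta_e,
        "true_ligand_distortion": true_distortion,
        "descriptor_model": {k: tuple(v) for k, v in model.items()},
    }
    values = {}
    for name, (base_v, slope, noise_sd) in model.items():
        values[name] = base_v + slope * true_distortion + rng.normal(0, noise_sd,
                                                                     config.n_conformers)
    truth.update({f"true_{k}": v for k, v in values.items()})

    homo = -0.30 + rng.normal(0, 0.002, config.n_conformers)
    lumo = homo + values["gap_ev"] / HARTREE_TO_EV
    frame = pd.DataFrame(
        {
            "member": np.arange(config.n_conformers),
            "energy_hartree": [m.energy for m in members],
            "homo_hartree": homo,
            "lumo_hartree": lumo,
        }
    )
    n_atoms = base.n_atoms
    charges = rng.normal(0.0, 0.05, size=(config.n_conformers, n_atoms))
    charges[:, complex_.spec.metal_index] = values["q_metal"]
    charges[:, complex_.spec.donor_indices[0]] = values["q_donor"]
    charges[:, complex_.spec.donor_indices[1]] = values["q_donor"]
    for a in range(n_atoms):
        frame[f"charge_{a}"] = charges[:, a]
    table = PropertyTable(frame=frame)
    return ensemble, table, truth


def mirror_structure(structure: Structure) -> Structure:
    """Reflect through the z = 0 plane: inverts chirality (and flips the
    quadrant family), for planting retention-filter violations."""
    coords = structure.coords.copy()
    coords[:, 2] *= -1
    return structure.with_coords(coords)


def flip_substrate_quadrant(structure: Structure, complex_: SyntheticComplex) -> Structure:
    """Move the directing-group reference atom to the mirror quadrant
    (major <-> minor) while leaving chirality intact.

    The reference atom's y-component in the local quadrant frame is negated,
    so the flip is exact in any orientation of the structure.
    """
    from .complexes import local_quadrant_frame

    ref = complex_.anchor_indices[2]
    origin, x, y, z = local_quadrant_frame(structure, complex_.spec, complex_.anchor_indices)
    r = structure.coords[ref] - origin
    px, py, pz = np.dot(r, x), np.dot(r, y), np.dot(r, z)
    coords = structure.coords.copy()
    coords[ref] = origin + px * x - py * y + pz * z
    return structure.with_coords(coords)


def make_dedup_fixture(
    config: GeneratorConfig,
    complex_: SyntheticComplex | None = None,
    stream: int = 2,
) -> tuple[ConformerEnsemble, dict]:
    """Ensemble of ``n_wells`` distinct minima, each replicated with jitter.

    Well centres are the base complex with independent large displacements of
    the flexible ligand arms, accepted only if all pairwise heavy-atom
    minimal RMSDs are >= ``well_separation``. Replicates add per-atom jitter
    (``config.jitter`` Å, far below any sane dedup tolerance) plus a random
    rigid motion; replicate energies cluster within ~0.02 kJ/mol of the well
    energy, and wells are spaced ``well_energy_gap_kj`` apart.

    Returns the shuffled ensemble and a truth dict with the planted well
    index per member.
    """
    from .rmsd import minimal_rmsd  # local import avoids a cycle at module load

    if config.well_separation <= 10 * config.jitter:
        raise ValueError("well_separation must exceed the jitter scale by a wide margin")
    rng = config.rng(stream)
    if complex_ is None:
        complex_ = make_complex_template(config)
    base = complex_.structure
    flex = list(complex_.flexible_ligand_indices)
    if not flex:
        raise ValueError("complex has no flexible atoms to build wells from")

    reps = config.replicates_per_well
    if isinstance(reps, int):
        reps_per_well = [reps] * config.n_wells
    else:
        if len(reps) != config.n_wells:
            raise ValueError("replicates_per_well sequence must have n_wells entries")
        reps_per_well = list(reps)

    centers: list[Structure] = []
    attempts = 0
    while len(centers) < config.n_wells:
        if attempts > 200 * config.n_wells:
            raise RuntimeError("could not separate well centres; increase well_separation")
        attempts += 1
        disp = np.zeros((base.n_atoms, 3))
        disp[flex] = rng.normal(0, config.well_separation, size=(len(flex), 3))
        candidate = base.with_coords(base.coords + disp)
        if all(minimal_rmsd(candidate, c).rmsd >= config.well_separation for c in centers):
            centers.append(candidate)

    members: list[Structure] = []
    well_of_member: list[int] = []
    for w, (center, r) in enumerate(zip(centers, reps_per_well)):
        e_well_kj = w * config.well_energy_gap_kj
        for _ in range(r):
            coords = center.coords + rng.normal(0, config.jitter, size=(base.n_atoms, 3))
            R, t = random_rigid_motion(rng)
            e_kj = e_well_kj + rng.normal(0, 0.02)
            members.append(
                Structure(
                    symbols=list(base.symbols),
                    coords=coords @ R.T + t,
                    energy=BASE_ENERGY_HARTREE + e_kj / HARTREE_TO_KJ_PER_MOL,
                    energy_unit="hartree",
                    label=f"well{w}",
                )
            )
            well_of_member.append(w)

    order = rng.permutation(len(members))
    baseline = Structure(
        symbols=list(base.symbols),
        coords=base.coords.copy(),
        energy=BASE_ENERGY_HARTREE,
        energy_unit="hartree",
        label="baseline",
    )
    ensemble = ConformerEnsemble(
        members=[members[i] for i in order],
        ligand_id=complex_.template.ligand_id,
        substrate_kind=complex_.template.substrate_kind,
        coordination_mode=complex_.template.coordination_mode,
        baseline=baseline,
        stage="dft",
    )
    truth = {"well_of_member": [well_of_member[i] for i in order], "n_wells": config.n_wells}
    return ensemble, truth


def write_dataset(
    out_dir: str | Path,
    config: GeneratorConfig,
    ligand_id: str = "L1",
    modes: tuple[str, ...] = ("major1", "major2", "minor1", "minor2", "nbd"),
) -> Path:
    """Write a full synthetic dataset in the layout the pipeline reads.

    One ensemble per coordination mode, each in crest-dialect XYZ with a
    baseline structure and a property table, plus the shared fragment spec,
    metadata and a truth record (JSON). Returns the dataset directory.
    """
    from .structures import write_ensemble_xyz, write_xyz

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    groups_meta = []
    truth_all: dict = {}
    spec_written = False
    chir = None
    anchors = None
    for stream, mode in enumerate(modes, start=1):
        complex_ = make_complex_template(config, ligand_id=ligand_id, coordination_mode=mode)
        if not spec_written:
            complex_.spec.to_yaml(root / "fragment_spec.yaml")
            spec_written = True
            chir = complex_.expected_chirality_sign
            anchors = complex_.anchor_indices
        ensemble, table, truth = make_ensemble(config, complex_, stream=stream)
        write_ensemble_xyz(ensemble, root / f"{mode}.xyz")
        base = ensemble.baseline
        write_xyz(base, root / f"{mode}_baseline.xyz",
                  comment=f"{base.energy:.10f}")
        table.to_csv(root / f"{mode}_properties.csv")
        groups_meta.append(
            {
                "coordination_mode": mode,
                "xyz": f"{mode}.xyz",
                "baseline_xyz": f"{mode}_baseline.xyz",
                "properties": f"{mode}_properties.csv",
            }
        )
        truth_all[mode] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in truth.items()
        }
    meta = {
        "ligand_id": ligand_id,
        "seed": config.seed,
        "anchor_indices": [int(i) for i in anchors],
        "expected_chirality_sign": int(chir),
        "chiral_reference": [3, 1, 2, 4],
        "groups": groups_meta,
    }
    (root / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    (root / "truth.json").write_text(json.dumps(truth_all, indent=1, sort_keys=True))
    return root
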