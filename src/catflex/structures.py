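"""Molecular structures, conformer ensembles and per-conformer property tables.

Geometry I/O is plain XYZ and concatenated multi-frame XYZ. The ``crest``
dialect follows the CREST ``crest_conformers.xyz`` convention: the first
whitespace-separated token of each frame's comment line is the frame energy
in hartree.

Electronic quantities (total energy, per-atom NPA charges, frontier-orbital
energies) are not computed here — they are ingested from a delimited property
table written by whatever quantum-chemistry post-processing produced them.
Schema (CSV with header):

    member         optional conformer label
    energy_hartree total electronic energy (hartree)
    homo_hartree   HOMO orbital energy (hartree)
    lumo_hartree   LUMO orbital energy (hartree)
    charge_<i>     NPA charge (au) of atom index i (0-based); only the metal
                   and donor atoms are required downstream
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .units import convert_energy

__all__ = [
    "Structure",
    "ConformerEnsemble",
    "PropertyTable",
    "XYZParseError",
    "EnsembleConsistencyError",
    "PropertyTableError",
    "read_xyz",
    "read_ensemble_xyz",
    "write_xyz",
    "write_ensemble_xyz",
    "ingest_property_table",
    "count_xyz_frames",
]

# Periodic-table symbols 1..103; enough for any input this pipeline meets.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr""".split()
)


class XYZParseError(ValueError):
    """Malformed XYZ content (bad atom-count line, short frame, bad coordinates)."""


class EnsembleConsistencyError(ValueError):
    """Frames of one ensemble disagree in element sequence or atom count."""


class PropertyTableError(ValueError):
    """Property table violates the schema or is misaligned with its ensemble."""


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an element symbol (``rh`` → ``Rh``) and validate it."""
    s = symbol.strip()
    if not s:
        raise XYZParseError("empty element symbol")
    s = s[0].upper() + s[1:].lower()
    if s not in ELEMENT_SYMBOLS:
        raise XYZParseError(f"unknown element symbol {symbol!r}")
    return s


@dataclass
class Structure:
    """One conformer geometry: element symbols plus Cartesian coordinates in Å.

    ``energy`` is optional; when set, ``energy_unit`` declares its unit
    (``hartree``, ``kJ/mol`` or ``kcal/mol``).
    """

    symbols: list[str]
    coords: np.ndarray
    energy: float | None = None
    energy_unit: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.symbols = [normalize_symbol(s) for s in self.symbols]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.energy is not None and self.energy_unit is None:
            raise ValueError("energy set without a declared unit")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def energy_in(self, unit: str) -> float:
        if self.energy is None:
            raise ValueError(f"structure {self.label!r} has no energy")
        return convert_energy(self.energy, self.energy_unit, unit)

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.symbols) if s != "H"], dtype=int)

    def subset(self, indices: Sequence[int], label: str = "") -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            symbols=[self.symbols[i] for i in idx],
            coords=self.coords[idx],
            energy=self.energy,
            energy_unit=self.energy_unit,
            label=label or self.label,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class ConformerEnsemble:
    """Ordered conformer set sharing one ligand/substrate/coordination provenance.

    ``baseline`` is the structure used as conformer-search input; its
    DFT energy anchors the ΔE scale of the ensemble. ``stage`` records
    whether member geometries/energies are raw search output (``crest``)
    or DFT-reoptimized (``dft``).
    """

    members: list[Structure]
    ligand_id: str = ""
    substrate_kind: str = "S"
    coordination_mode: str = "major1"
    baseline: Structure | None = None
    stage: str = "dft"

    def __post_init__(self) -> None:
        if self.substrate_kind not in ("S", "NBD"):
            raise ValueError(f"substrate_kind must be S or NBD, got {self.substrate_kind!r}")
        if self.coordination_mode not in ("major1", "major2", "minor1", "minor2", "nbd"):
            raise ValueError(f"invalid coordination_mode {self.coordination_mode!r}")
        if self.stage not in ("crest", "dft"):
            raise ValueError(f"stage must be crest or dft, got {self.stage!r}")
        if self.members:
            ref = self.members[0].symbols
            for i, m in enumerate(self.members):
                if m.symbols != ref:
                    raise EnsembleConsistencyError(
                        f"member {i} element sequence differs from member 0"
                    )
        if self.stage == "dft" and self.baseline is not None and self.baseline.energy is None:
            raise ValueError("a dft-stage ensemble baseline must carry an energy")

    def __len__(self) -> int:
        return len(self.members)

    def energies_in(self, unit: str) -> np.ndarray:
        return np.array([m.energy_in(unit) for m in self.members])

    def lowest_energy_index(self) -> int:
        """Index of the minimum-energy member; ties broken by lowest index."""
        e = self.energies_in("hartree")
        return int(np.argmin(e))

    def replace_members(self, members: list[Structure]) -> "ConformerEnsemble":
        return ConformerEnsemble(
            members=members,
            ligand_id=self.ligand_id,
            substrate_kind=self.substrate_kind,
            coordination_mode=self.coordination_mode,
            baseline=self.baseline,
            stage=self.stage,
        )


# ---------------------------------------------------------------------------
# XYZ input/output


def _parse_frames(lines: list[str], path: str) -> Iterable[tuple[int, str, list[str], np.ndarray]]:
    pos = 0
    frame = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"{path}: frame {frame}: atom-count line {pos + 1} is not an integer: "
                f"{lines[pos].strip()!r}"
            ) from exc
        if natoms <= 0:
            raise XYZParseError(f"{path}: frame {frame}: non-positive atom count {natoms}")
        if pos + 2 + natoms > n_lines:
            raise XYZParseError(f"{path}: frame {frame}: truncated (expected {natoms} atoms)")
        comment = lines[pos + 1].rstrip("\n")
        symbols: list[str] = []
        rows = np.empty((natoms, 3))
        for i in range(natoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: frame {frame}: atom line {pos + 3 + i} has {len(parts)} fields"
                )
            symbols.append(parts[0])
            try:
                rows[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise XYZParseError(
                    f"{path}: frame {frame}: bad coordinate on line {pos + 3 + i}"
                ) from exc
        yield frame, comment, symbols, rows
        pos += 2 + natoms
        frame += 1


def read_xyz(path: str | Path) -> Structure:
    """Read a single-structure XYZ file (first frame if several)."""
    lines = Path(path).read_text().splitlines()
    for _, comment, symbols, coords in _parse_frames(lines, str(path)):
        return Structure(symbols=symbols, coords=coords, label=comment.strip())
    raise XYZParseError(f"{path}: no frames found")


def read_ensemble_xyz(
    path: str | Path,
    dialect: str = "crest",
    **ensemble_kwargs,
) -> ConformerEnsemble:
    """Read a concatenated multi-frame XYZ file as a conformer ensemble.

    ``dialect='crest'``: the first token of each comment line is parsed as the
    frame energy in hartree. ``dialect='plain'``: energies are left unset.
    Atom ordering and element sequence must be identical across frames.
    """
    if dialect not in ("plain", "crest"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = Path(path).read_text().splitlines()
    members: list[Structure] = []
    for frame, comment, symbols, coords in _parse_frames(lines, str(path)):
        energy = None
        unit = None
        if dialect == "crest":
            tokens = comment.split()
            if not tokens:
                raise XYZParseError(f"{path}: frame {frame}: empty comment line in crest dialect")
            try:
                energy = float(tokens[0])
            except ValueError as exc:
                raise XYZParseError(
                    f"{path}: frame {frame}: comment token {tokens[0]!r} is not an energy"
                ) from exc
            unit = "hartree"
        members.append(
            Structure(symbols=symbols, coords=coords, energy=energy, energy_unit=unit,
                      label=f"frame{frame}")
        )
    if not members:
        raise XYZParseError(f"{path}: no frames found")
    return ConformerEnsemble(members=members, **ensemble_kwargs)


def _format_frame(structure: Structure, comment: str) -> str:
    out = [str(structure.n_atoms), comment]
    for sym, (x, y, z) in zip(structure.symbols, structure.coords):
        out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(out)


def write_xyz(structure: Structure, path: str | Path, comment: str | None = None) -> None:
    if comment is None:
        comment = structure.label
    Path(path).write_text(_format_frame(structure, comment) + "\n")


def write_ensemble_xyz(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as concatenated XYZ, crest dialect when energies exist."""
    frames = []
    for m in ensemble.members:
        comment = f"{m.energy_in('hartree'):.10f}" if m.energy is not None else m.label
        frames.append(_format_frame(m, comment))
    Path(path).write_text("\n".join(frames) + "\n")


def count_xyz_frames(path: str | Path) -> int:
    """Frame count via the natoms headers, without building Structure objects."""
    lines = Path(path).read_text().splitlines()
    return sum(1 for _ in _parse_frames(lines, str(path)))


# ---------------------------------------------------------------------------
# Property tables

REQUIRED_PROPERTY_COLUMNS = ("energy_hartree", "homo_hartree", "lumo_hartree")


@dataclass
class PropertyTable:
    """Per-conformer electronic quantities, index-aligned with an ensemble.

    Wraps a DataFrame with one row per ensemble member in member order.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_PROPERTY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise PropertyTableError(f"property table missing required columns: {missing}")
        bad = self.frame["lumo_hartree"] <= self.frame["homo_hartree"]
        if bool(bad.any()):
            rows = list(self.frame.index[bad][:5])
            raise PropertyTableError(f"LUMO energy must exceed HOMO energy; violated at rows {rows}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def energies_hartree(self) -> np.ndarray:
        return self.frame["energy_hartree"].to_numpy()

    def charge(self, atom_index: int) -> np.ndarray:
        col = f"charge_{atom_index}"
        if col not in self.frame.columns:
            raise PropertyTableError(f"property table has no charge column for atom {atom_index}")
        return self.frame[col].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def ingest_property_table(path: str | Path, ensemble: ConformerEnsemble) -> PropertyTable:
    """Load a delimited property table and align it with an ensemble.

    Row count must equal the ensemble size; rows correspond to members in
    order. Required columns and the HOMO<LUMO constraint are validated.
    """
    frame = pd.read_csv(path)
    if len(frame) != len(ensemble):
        raise PropertyTableError(
            f"property table {path} has {len(frame)} rows but the ensemble has "
            f"{len(ensemble)} members"
        )
    return PropertyTable(frame=frame.reset_index(drop=True))
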