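"""Catalyst–substrate complex model.

A Rh–bisphosphine complex is partitioned by atom role: the metal centre, the
two phosphorus donor atoms, the remaining bidentate-ligand atoms, and the
bound substrate (either the prochiral enamide ester "S" or the norbornadiene
placeholder "NBD"). The substrate can bind in four orientations inside the
C2-chiral ligand pocket — two "major" (less hindered) and two "minor" (more
hindered) quadrant placements in the Knowles quadrant picture — while NBD,
being symmetric, has a single mode.

This module enumerates ligand × coordination-mode templates, splits a
conformer into ligand and substrate parts for independent flexibility
analysis, classifies which quadrant the substrate's directing group occupies,
and checks that the ligand's axial chirality survived conformer generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .structures import Structure

__all__ = [
    "FragmentSpec",
    "ComplexTemplate",
    "CoordinationAmbiguityError",
    "GeometryError",
    "S_COORDINATION_MODES",
    "ALL_COORDINATION_MODES",
    "enumerate_complexes",
    "split_fragments",
    "fragment_indices",
    "classify_coordination",
    "check_chirality",
    "dihedral_angle",
]

S_COORDINATION_MODES = ("major1", "major2", "minor1", "minor2")
ALL_COORDINATION_MODES = S_COORDINATION_MODES + ("nbd",)


class CoordinationAmbiguityError(ValueError):
    """Quadrant reference atom lies (numerically) on a boundary plane."""


class GeometryError(ValueError):
    """Degenerate geometry (collinear atoms, zero-length frame vectors)."""


@dataclass(frozen=True)
class FragmentSpec:
    """Role assignment of atom indices within one complex (0-based).

    The metal belongs to neither fragment list; it is re-attached to both
    parts on splitting. The two donor indices are the phosphorus atoms and
    must be members of the ligand.
    """

    metal_index: int
    donor_indices: tuple[int, int]
    ligand_indices: tuple[int, ...]
    substrate_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor_indices", tuple(self.donor_indices))
        object.__setattr__(self, "ligand_indices", tuple(self.ligand_indices))
        object.__setattr__(self, "substrate_indices", tuple(self.substrate_indices))
        lig = set(self.ligand_indices)
        sub = set(self.substrate_indices)
        if len(self.donor_indices) != 2:
            raise ValueError("exactly two donor atoms are required")
        if lig & sub:
            raise ValueError(f"ligand and substrate overlap at indices {sorted(lig & sub)}")
        if self.metal_index in lig | sub:
            raise ValueError("metal index must not appear in ligand or substrate")
        if not set(self.donor_indices) <= lig:
            raise ValueError("donor indices must be ligand atoms")
        if len(lig) != len(self.ligand_indices) or len(sub) != len(self.substrate_indices):
            raise ValueError("duplicate indices in fragment lists")
        if not sub:
            raise ValueError("substrate fragment is empty")

    @property
    def n_atoms(self) -> int:
        return len(self.ligand_indices) + len(self.substrate_indices) + 1

    def validate_for(self, structure: Structure) -> None:
        covered = set(self.ligand_indices) | set(self.substrate_indices) | {self.metal_index}
        n = structure.n_atoms
        if max(covered) >= n or min(covered) < 0:
            raise ValueError(
                f"fragment spec indices out of range for a {n}-atom structure"
            )
        if covered != set(range(n)):
            missing = sorted(set(range(n)) - covered)
            raise ValueError(f"fragment spec does not cover atoms {missing}")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "metal_index": int(self.metal_index),
            "donor_indices": [int(i) for i in self.donor_indices],
            "ligand_indices": [int(i) for i in self.ligand_indices],
            "substrate_indices": [int(i) for i in self.substrate_indices],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FragmentSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            metal_index=data["metal_index"],
            donor_indices=tuple(data["donor_indices"]),
            ligand_indices=tuple(data["ligand_indices"]),
            substrate_indices=tuple(data["substrate_indices"]),
        )


@dataclass(frozen=True)
class ComplexTemplate:
    """One ligand × substrate × coordination-mode combination.

    ``chiral_reference`` is the ordered 4-tuple of atom indices whose dihedral
    sign encodes the ligand's axial chirality.
    """

    ligand_id: str
    substrate_kind: str
    coordination_mode: str
    chiral_reference: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.substrate_kind not in ("S", "NBD"):
            raise ValueError(f"substrate_kind must be S or NBD, got {self.substrate_kind!r}")
        if self.coordination_mode not in ALL_COORDINATION_MODES:
            raise ValueError(f"invalid coordination mode {self.coordination_mode!r}")
        if (self.substrate_kind == "NBD") != (self.coordination_mode == "nbd"):
            raise ValueError("substrate_kind NBD if and only if coordination_mode nbd")


def enumerate_complexes(
    ligand_ids: Sequence[str], substrate_kinds: Sequence[str]
) -> list[ComplexTemplate]:
    """Enumerate templates: four S coordination modes and/or one NBD per ligand.

    Deterministic order: ligands in given order, then major1, major2, minor1,
    minor2, nbd.
    """
    if not ligand_ids:
        raise ValueError("ligand_ids is empty")
    if len(set(ligand_ids)) != len(ligand_ids):
        raise ValueError("duplicate ligand ids")
    kinds = set(substrate_kinds)
    unknown = kinds - {"S", "NBD"}
    if unknown:
        raise ValueError(f"unknown substrate kinds {sorted(unknown)}")
    templates: list[ComplexTemplate] = []
    for lig in ligand_ids:
        if "S" in kinds:
            for mode in S_COORDINATION_MODES:
                templates.append(ComplexTemplate(lig, "S", mode))
        if "NBD" in kinds:
            templates.append(ComplexTemplate(lig, "NBD", "nbd"))
    return templates


def fragment_indices(spec: FragmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Atom indices of the two analysis parts, in original index order.

    ligand part = ligand atoms + metal; substrate part = substrate atoms +
    metal + the two donors (the donors give the substrate an orientation
    reference in the otherwise ligand-free part).
    """
    lig = np.array(sorted(set(spec.ligand_indices) | {spec.metal_index}), dtype=int)
    sub = np.array(
        sorted(set(spec.substrate_indices) | {spec.metal_index} | set(spec.donor_indices)),
        dtype=int,
    )
    return lig, sub


def split_fragments(structure: Structure, spec: FragmentSpec) -> tuple[Structure, Structure]:
    """Split one conformer into its ligand part and substrate part."""
    spec.validate_for(structure)
    lig_idx, sub_idx = fragment_indices(spec)
    label = structure.label
    return (
        structure.subset(lig_idx, label=f"{label}|ligand" if label else "ligand"),
        structure.subset(sub_idx, label=f"{label}|substrate" if label else "substrate"),
    )


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise GeometryError(f"degenerate geometry: zero-length {what} vector")
    return v / n


def local_quadrant_frame(
    structure: Structure, spec: FragmentSpec, anchor_indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (x, y, z) at the metal centre.

    x: bisector of the two metal→donor unit vectors.
    z: normal of the donor–metal–donor plane, oriented toward the substrate
       (the midpoint of the two coordinating anchor atoms), which makes the
       frame independent of donor ordering.
    y: z × x, completing the right-handed frame.

    Returns (origin, x, y, z).
    """
    c1, c2, _ = anchor_indices
    m = structure.coords[spec.metal_index]
    u1 = _unit(structure.coords[spec.donor_indices[0]] - m, "metal-donor")
    u2 = _unit(structure.coords[spec.donor_indices[1]] - m, "metal-donor")
    x = _unit(u1 + u2, "donor bisector")
    z = _unit(np.cross(u1, u2), "donor-plane normal")
    mid = 0.5 * (structure.coords[c1] + structure.coords[c2])
    if np.dot(z, mid - m) < 0:
        z = -z
    y = np.cross(z, x)
    return m, x, y, z


def classify_coordination(
    structure: Structure,
    spec: FragmentSpec,
    anchor_indices: Sequence[int],
    major_positive_y: bool = True,
    boundary_tol: float = 1e-3,
) -> str:
    """Assign the substrate coordination mode from the quadrant occupied by
    the out-of-plane reference atom (the directing-group oxygen).

    ``anchor_indices`` is ``(c1, c2, ref)``: the two metal-coordinated alkene
    carbons (their midpoint orients the frame's out-of-plane axis toward the
    substrate, making the frame donor-order independent) and the reference
    atom whose (x, y) projection signs select the quadrant. The y-sign
    distinguishes major from minor (convention flag ``major_positive_y``);
    the x-sign distinguishes modes 1 and 2. A projection within
    ``boundary_tol`` Å of a boundary plane raises rather than silently
    picking a side.
    """
    if len(anchor_indices) != 3:
        raise ValueError("anchor_indices must be (carbon1, carbon2, reference)")
    ref = anchor_indices[2]
    origin, x, y, _ = local_quadrant_frame(structure, spec, anchor_indices)
    r = structure.coords[ref] - origin
    px = float(np.dot(r, x))
    py = float(np.dot(r, y))
    if abs(px) < boundary_tol or abs(py) < boundary_tol:
        raise CoordinationAmbiguityError(
            f"reference atom {ref} projects to ({px:.4f}, {py:.4f}) Å, within "
            f"{boundary_tol} Å of a quadrant boundary"
        )
    is_major = (py > 0) == major_positive_y
    family = "major" if is_major else "minor"
    which = "1" if px > 0 else "2"
    return family + which


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees over four points (IUPAC sign)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("collinear atoms in dihedral reference")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return float(ang)


def check_chirality(
    structure: Structure,
    chiral_reference: Sequence[int],
    expected_sign: int,
) -> bool:
    """True iff the sign of the axial-chirality dihedral matches expectation.

    The dihedral sign flips under reflection and is invariant under proper
    rigid motion, so it detects conformers whose stereochemistry was inverted
    during ensemble generation.
    """
    if expected_sign not in (-1, 1):
        raise ValueError("expected_sign must be +1 or -1")
    i, j, k, l = chiral_reference
    ang = dihedral_angle(
        structure.coords[i], structure.coords[j], structure.coords[k], structure.coords[l]
    )
    return (1 if ang > 0 else -1) == expected_sign
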