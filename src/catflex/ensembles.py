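"""Ensemble-level statistics and filters.

Covers the bookkeeping that turns a raw conformer-search output into an
analysable ensemble: energies relative to the conformer-search input
structure (the "baseline"), the energy-window selection applied to search
output, deduplication of conformers that converged to the same minimum after
re-optimization, and the retention filters (chirality preserved, substrate
still bound in its initial coordination mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .complexes import (
    ComplexTemplate,
    CoordinationAmbiguityError,
    FragmentSpec,
    check_chirality,
    classify_coordination,
)
from .rmsd import minimal_rmsd, rmsd_profile
from .structures import ConformerEnsemble

__all__ = [
    "EnsembleSummary",
    "RemovalRecord",
    "relative_energies",
    "energy_window_filter",
    "deduplicate",
    "apply_retention_filters",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class RemovalRecord:
    """One retention-filter event: which member, why, with detail."""

    member_index: int
    reason: str  # 'chirality' | 'coordination' | 'flagged:ambiguous-coordination'
    detail: str = ""

    @property
    def removed(self) -> bool:
        return not self.reason.startswith("flagged")


@dataclass
class EnsembleSummary:
    """Headline numbers for one (ligand, substrate, coordination-mode) set."""

    ligand_id: str
    substrate_kind: str
    coordination_mode: str
    n_crest: int
    n_distinct_dft: int
    delta_e_range_kj: tuple[float, float]
    rmsd_range_whole: tuple[float, float] = (np.nan, np.nan)
    rmsd_range_ligand: tuple[float, float] = (np.nan, np.nan)
    rmsd_range_substrate: tuple[float, float] = (np.nan, np.nan)
    n_removed_chirality: int = 0
    n_removed_coordination: int = 0

    def __post_init__(self) -> None:
        if self.n_distinct_dft > self.n_crest:
            raise ValueError("n_distinct_dft cannot exceed n_crest")


def relative_energies(ensemble: ConformerEnsemble) -> np.ndarray:
    """Per-member energy minus the baseline (conformer-search input) energy,
    in kJ/mol. Negative values mean the search found conformers more stable
    than the structure it started from."""
    if ensemble.baseline is None or ensemble.baseline.energy is None:
        raise ValueError("ensemble has no baseline energy")
    e_base = ensemble.baseline.energy_in("kJ/mol")
    return ensemble.energies_in("kJ/mol") - e_base


def energy_window_filter(
    ensemble: ConformerEnsemble, window_kcal: float = 6.0
) -> ConformerEnsemble:
    """Keep members within ``window_kcal`` of the ensemble minimum energy.

    The window is expressed in kcal/mol (the conformer-search selection
    convention); the minimum is recomputed over the input members. The
    boundary is inclusive.
    """
    if window_kcal < 0:
        raise ValueError("window must be non-negative")
    e = ensemble.energies_in("kcal/mol")
    keep = e - e.min() <= window_kcal + 1e-12
    return ensemble.replace_members([m for m, k in zip(ensemble.members, keep) if k])


def deduplicate(
    ensemble: ConformerEnsemble,
    rmsd_tol: float = 0.25,
    energy_tol_kj: float = 1.0,
) -> ConformerEnsemble:
    """Merge members that converged to the same minimum.

    Greedy clustering in ascending energy order: a member joins an existing
    representative when its heavy-atom minimal RMSD to that representative is
    <= ``rmsd_tol`` (Å) AND its energy is within ``energy_tol_kj`` (kJ/mol).
    Because members are visited in ascending energy, each representative is
    its cluster's energy minimum. Output is sorted by energy.

    Idempotent: representatives of a deduplicated ensemble are pairwise
    farther apart than the tolerances, so a second pass is the identity.
    """
    if rmsd_tol <= 0 or energy_tol_kj <= 0:
        raise ValueError("tolerances must be positive")
    if not ensemble.members:
        return ensemble
    e = ensemble.energies_in("kJ/mol")
    order = np.lexsort((np.arange(len(e)), e))  # ascending energy, index tiebreak
    reps: list[int] = []
    for i in order:
        merged = False
        for r in reps:
            if abs(e[i] - e[r]) <= energy_tol_kj:
                res = minimal_rmsd(ensemble.members[r], ensemble.members[i],
                                   exclude_hydrogens=True)
                if res.rmsd <= rmsd_tol:
                    merged = True
                    break
        if not merged:
            reps.append(int(i))
    return ensemble.replace_members([ensemble.members[r] for r in reps])


def apply_retention_filters(
    ensemble: ConformerEnsemble,
    template: ComplexTemplate,
    spec: FragmentSpec,
    anchor_indices: Sequence[int] | None = None,
    expected_chirality_sign: int | None = None,
    major_positive_y: bool = True,
) -> tuple[ConformerEnsemble, list[RemovalRecord]]:
    """Drop members that inverted chirality or left the initial coordination mode.

    The chirality check runs when the template carries a ``chiral_reference``
    and ``expected_chirality_sign`` is given. The coordination check runs for
    substrate-bound (non-NBD) templates when ``anchor_indices`` is given; a
    member the classifier cannot assign unambiguously is *flagged* in the log
    but retained — silent removal of borderline geometries would bias the
    ensemble.
    """
    log: list[RemovalRecord] = []
    kept = []
    check_coord = anchor_indices is not None and template.coordination_mode != "nbd"
    check_chir = template.chiral_reference is not None and expected_chirality_sign is not None
    for i, member in enumerate(ensemble.members):
        if check_chir and not check_chirality(
            member, template.chiral_reference, expected_chirality_sign
        ):
            log.append(RemovalRecord(i, "chirality", "axial dihedral sign inverted"))
            continue
        if check_coord:
            try:
                mode = classify_coordination(
                    member, spec, anchor_indices, major_positive_y=major_positive_y
                )
            except CoordinationAmbiguityError as exc:
                log.append(RemovalRecord(i, "flagged:ambiguous-coordination", str(exc)))
                kept.append(member)
                continue
            if mode != template.coordination_mode:
                log.append(
                    RemovalRecord(i, "coordination", f"classified as {mode}, "
                                  f"expected {template.coordination_mode}")
                )
                continue
        kept.append(member)
    return ensemble.replace_members(kept), log


def _range(values: np.ndarray) -> tuple[float, float]:
    return (float(np.min(values)), float(np.max(values))) if len(values) else (np.nan, np.nan)


def summarize_ensemble(
    crest_ensemble: ConformerEnsemble,
    dft_ensemble: ConformerEnsemble,
    spec: FragmentSpec | None = None,
    removal_log: Sequence[RemovalRecord] = (),
) -> EnsembleSummary:
    """Collect the per-set headline numbers (counts, ΔE range, rmsd ranges)."""
    if dft_ensemble.baseline is not None and dft_ensemble.baseline.energy is not None:
        de = relative_energies(dft_ensemble)
    else:
        e = dft_ensemble.energies_in("kJ/mol")
        de = e - e.min()
    summary = EnsembleSummary(
        ligand_id=dft_ensemble.ligand_id,
        substrate_kind=dft_ensemble.substrate_kind,
        coordination_mode=dft_ensemble.coordination_mode,
        n_crest=len(crest_ensemble),
        n_distinct_dft=len(dft_ensemble),
        delta_e_range_kj=_range(de),
        n_removed_chirality=sum(1 for r in removal_log if r.reason == "chirality"),
        n_removed_coordination=sum(1 for r in removal_log if r.reason == "coordination"),
    )
    if len(dft_ensemble) and spec is not None:
        profile = rmsd_profile(dft_ensemble, spec)
        summary.rmsd_range_whole = _range(profile["rmsd_whole"].to_numpy())
        summary.rmsd_range_ligand = _range(profile["rmsd_ligand"].to_numpy())
        summary.rmsd_range_substrate = _range(profile["rmsd_substrate"].to_numpy())
    return summary
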