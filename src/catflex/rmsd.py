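"""Minimal RMSD between conformers by optimal rigid superposition.

Uses the Kabsch algorithm (closed-form least-squares proper rotation after
centroid removal). Reflections are never permitted: the systems analysed are
chiral, and an improper superposition would silently match a conformer onto
its enantiomer. Atom correspondence is positional — every member of an
ensemble derives from the same input structure, so atom ordering is stable
and no graph matching is attempted. Hydrogens are excluded by default, since
rotating methyls and the like would otherwise dominate the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complexes import FragmentSpec, fragment_indices
from .structures import ConformerEnsemble, Structure

__all__ = ["RMSDResult", "kabsch_superpose", "minimal_rmsd", "rmsd_profile"]


@dataclass(frozen=True)
class RMSDResult:
    """Optimal superposition result.

    ``rotation`` and ``translation`` map the second point set onto the first:
    ``Q @ rotation.T + translation ≈ P``.
    """

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    atoms_used: int


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> RMSDResult:
    """Least-squares proper-rotation superposition of Q onto P.

    Both inputs are (n, 3) coordinate arrays with positional correspondence,
    n >= 3. The returned rotation always has determinant +1; if the optimal
    orthogonal transform would be a reflection, the best proper rotation is
    returned instead (standard determinant-correction of the SVD solution).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate shapes differ: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinates must have shape (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 atoms are required for superposition, got {n}")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    cov = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # rank-deficient covariance; fall back to proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    residual = Pc - Qc @ R.T
    rmsd = float(np.sqrt((residual**2).sum() / n))
    return RMSDResult(rmsd=rmsd, rotation=R, translation=t, atoms_used=n)


def minimal_rmsd(
    a: Structure,
    b: Structure,
    exclude_hydrogens: bool = True,
    mask: np.ndarray | None = None,
) -> RMSDResult:
    """Minimal RMSD between two equally-ordered structures.

    ``mask`` (atom indices into the full structures) is applied first, then
    hydrogens are dropped when ``exclude_hydrogens``. At least 3 atoms must
    survive the filtering.
    """
    if a.symbols != b.symbols:
        raise ValueError("structures do not share an element sequence")
    idx = np.arange(a.n_atoms) if mask is None else np.asarray(mask, dtype=int)
    if mask is not None and (idx.min(initial=0) < 0 or idx.max(initial=-1) >= a.n_atoms):
        raise ValueError("mask indices out of range")
    if exclude_hydrogens:
        idx = np.array([i for i in idx if a.symbols[i] != "H"], dtype=int)
    if len(idx) < 3:
        raise ValueError(
            f"only {len(idx)} atoms survive masking/hydrogen exclusion; need >= 3"
        )
    return kabsch_superpose(a.coords[idx], b.coords[idx])


def rmsd_profile(
    ensemble: ConformerEnsemble,
    spec: FragmentSpec | None = None,
    reference_index: int | None = None,
    exclude_hydrogens: bool = True,
) -> pd.DataFrame:
    """Per-member minimal RMSD to the lowest-energy conformer.

    Whole-complex RMSD always; ligand-part and substrate-part RMSD when a
    fragment spec is given (each part superposed independently, so e.g. a
    rigid substrate scores near zero even while the ligand rearranges).
    The reference is the minimum-energy member (energy ties broken by lowest
    member index) unless ``reference_index`` overrides it; the reference row
    is identically zero.

    Returns a DataFrame with columns ``member``, ``delta_e_kj`` (energy above
    the ensemble minimum) and ``rmsd_whole`` [, ``rmsd_ligand``,
    ``rmsd_substrate``] in Å.
    """
    if not ensemble.members:
        raise ValueError("empty ensemble")
    energies = ensemble.energies_in("kJ/mol")
    ref_i = ensemble.lowest_energy_index() if reference_index is None else int(reference_index)
    ref = ensemble.members[ref_i]
    if spec is not None:
        spec.validate_for(ref)
        lig_idx, sub_idx = fragment_indices(spec)

    rows = []
    for i, member in enumerate(ensemble.members):
        row: dict[str, object] = {
            "member": i,
            "delta_e_kj": energies[i] - energies[ref_i],
            "rmsd_whole": minimal_rmsd(ref, member, exclude_hydrogens).rmsd,
        }
        if spec is not None:
            row["rmsd_ligand"] = minimal_rmsd(ref, member, exclude_hydrogens, mask=lig_idx).rmsd
            row["rmsd_substrate"] = minimal_rmsd(ref, member, exclude_hydrogens, mask=sub_idx).rmsd
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["reference_index"] = ref_i
    return frame
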