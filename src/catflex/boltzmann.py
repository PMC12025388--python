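"""Group-wise Boltzmann weighting of conformer descriptor values.

Each conformer i receives a raw weight

    w_i = exp(-(E_i - E_min) / (k_B T))

with E_min the minimum energy *within the conformer's group*, so the
minimum-energy member of every group has raw weight 1. Groups follow the
three-way pooling used for reporting: the two major coordination-mode sets
pool into "S-major", the two minor sets into "S-minor", and the
norbornadiene precatalyst ensemble forms "NBD". Energies are handled in
kJ/mol with the molar gas constant as k_B, which is identical to the
per-molecule form.

The default working temperature is 289 K; it is a plain keyword argument
everywhere (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .units import GAS_CONSTANT_KJ_PER_MOL_K

__all__ = [
    "BoltzmannSpec",
    "boltzmann_weights",
    "weighted_stats",
    "group_weights",
    "group_summary",
    "pool_coordination_modes",
    "DEFAULT_TEMPERATURE_K",
]

DEFAULT_TEMPERATURE_K = 289.0

#: reporting pools: coordination-mode set -> descriptor-averaging group
_MODE_POOL = {
    "major1": "S-major",
    "major2": "S-major",
    "minor1": "S-minor",
    "minor2": "S-minor",
    "nbd": "NBD",
}


def pool_coordination_modes(modes: Sequence[str]) -> list[str]:
    """Map per-member coordination-mode labels to the three reporting groups."""
    try:
        return [_MODE_POOL[m] for m in modes]
    except KeyError as exc:
        raise ValueError(f"unknown coordination mode {exc.args[0]!r}") from None


@dataclass(frozen=True)
class BoltzmannSpec:
    """Weighting parameters: temperature and the member → group partition."""

    temperature: float = DEFAULT_TEMPERATURE_K
    grouping: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def boltzmann_weights(
    energies_kj: np.ndarray, temperature: float = DEFAULT_TEMPERATURE_K
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized Boltzmann weights for one group of conformers.

    Energies in kJ/mol. The minimum-energy member has raw weight 1; the
    normalized weights sum to 1.
    """
    e = np.asarray(energies_kj, dtype=float)
    if e.size == 0:
        raise ValueError("empty group")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = GAS_CONSTANT_KJ_PER_MOL_K * temperature
    w = np.exp(-(e - e.min()) / kt)
    return w, w / w.sum()


def weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean and population weighted standard deviation.

    ``weights`` must be normalized (sum 1 within 1e-10).
    std = sqrt(sum_i w_i (v_i - mean)^2); zero when all values coincide.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError(f"values and weights differ in length: {v.shape} vs {w.shape}")
    if abs(w.sum() - 1.0) > 1e-10:
        raise ValueError("weights are not normalized")
    mean = float(np.dot(w, v))
    var = float(np.dot(w, (v - mean) ** 2))
    return mean, float(np.sqrt(max(var, 0.0)))


def group_weights(
    energies_kj: np.ndarray,
    groups: Sequence[str],
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> np.ndarray:
    """Normalized weights computed independently within each group.

    E_min is taken per group; the returned array sums to 1 within each group.
    """
    e = np.asarray(energies_kj, dtype=float)
    if len(groups) != e.size:
        raise ValueError("groups and energies differ in length")
    out = np.empty_like(e)
    for g in dict.fromkeys(groups):  # preserve first-appearance order
        mask = np.array([gi == g for gi in groups])
        _, out[mask] = boltzmann_weights(e[mask], temperature)
    return out


def group_summary(
    descriptor_frame: pd.DataFrame,
    energies_kj: np.ndarray,
    groups: Sequence[str],
    temperature: float = DEFAULT_TEMPERATURE_K,
    descriptor_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boltzmann-weighted mean ± std of every descriptor, per group.

    ``descriptor_frame`` has one row per member; ``groups`` assigns each
    member to exactly one averaging group. Returns a tidy frame with columns
    ``group, descriptor, mean, std, n, ess`` where ess = 1 / sum(w^2) is the
    effective number of contributing conformers.
    """
    e = np.asarray(energies_kj, dtype=float)
    if len(descriptor_frame) != e.size or len(groups) != e.size:
        raise ValueError("descriptor frame, energies and groups must be aligned")
    if descriptor_columns is None:
        descriptor_columns = [
            c for c in descriptor_frame.columns
            if c != "member" and np.issubdtype(descriptor_frame[c].dtype, np.number)
        ]
    rows = []
    garr = np.asarray(groups, dtype=object)
    for g in dict.fromkeys(groups):
        mask = garr == g
        _, w = boltzmann_weights(e[mask], temperature)
        ess = float(1.0 / np.sum(w**2))
        for col in descriptor_columns:
            mean, std = weighted_stats(descriptor_frame.loc[mask, col].to_numpy(), w)
            rows.append(
                {"group": g, "descriptor": col, "mean": mean, "std": std,
                 "n": int(mask.sum()), "ess": ess}
            )
    return pd.DataFrame(rows)
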