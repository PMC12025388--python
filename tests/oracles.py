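"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they validate: the RMSD oracles go
through scipy's rotation machinery or a dense grid search over rotation
space, and the buried-volume oracle is Monte-Carlo rejection sampling.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def grid_search_rmsd(P: np.ndarray, Q: np.ndarray, final_step: float = 0.1) -> float:
    """Minimal RMSD by dense search over rotation space.

    Coarse scan over a full Euler-angle grid, then iterative local zoom down
    to ``final_step`` degrees. Suitable for small point sets only.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def scan(centers: np.ndarray, step: float, half_width: int) -> tuple[np.ndarray, float]:
        offs = np.arange(-half_width, half_width + 1) * step
        aa, bb, cc = np.meshgrid(
            centers[0] + offs, centers[1] + offs, centers[2] + offs, indexing="ij"
        )
        angles = np.column_stack([aa.ravel(), bb.ravel(), cc.ravel()])
        mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        rotated = np.einsum("rij,nj->rni", mats, Qc)
        rms = np.sqrt(((rotated - Pc[None]) ** 2).sum(axis=(1, 2)) / len(Pc))
        k = int(np.argmin(rms))
        return angles[k], float(rms[k])

    # full coarse sweep at 6 degrees
    coarse = np.arange(0.0, 360.0, 6.0)
    aa, bb, cc = np.meshgrid(coarse, np.arange(0.0, 180.0 + 6.0, 6.0), coarse, indexing="ij")
    angles = np.column_stack([aa.ravel(), bb.ravel(), cc.ravel()])
    mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
    rotated = np.einsum("rij,nj->rni", mats, Qc)
    rms = np.sqrt(((rotated - Pc[None]) ** 2).sum(axis=(1, 2)) / len(Pc))
    best_angles = angles[int(np.argmin(rms))]
    best = float(rms.min())

    step = 6.0
    while step > final_step:
        step = max(step / 4.0, final_step)
        best_angles, best = scan(best_angles, step, half_width=6)
    return best


def scipy_align_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD via scipy's Kabsch (Rotation.align_vectors)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Pc, Qc)
    return float(np.sqrt(((rot.apply(Qc) - Pc) ** 2).sum() / len(Pc)))


def monte_carlo_buried_volume(
    coords: np.ndarray,
    radii: np.ndarray,
    center: np.ndarray,
    sphere_radius: float,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Percent buried volume by rejection sampling; returns (estimate, SE)
    in percentage points."""
    n_in = 0
    n_buried = 0
    chunk = 1_000_000
    remaining = n_samples
    rel = coords - center
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        pts = rng.uniform(-sphere_radius, sphere_radius, size=(m, 3))
        inside = (pts**2).sum(axis=1) <= sphere_radius**2
        pts = pts[inside]
        n_in += len(pts)
        buried = np.zeros(len(pts), dtype=bool)
        for p, r in zip(rel, radii):
            buried |= ((pts - p) ** 2).sum(axis=1) <= r * r
        n_buried += int(buried.sum())
    frac = n_buried / n_in
    se = np.sqrt(frac * (1 - frac) / n_in)
    return 100.0 * frac, 100.0 * se
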