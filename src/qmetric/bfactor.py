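"""Atomic B factors from Q-scores via an optimized scaling factor.

Each atom's B factor is taken as ``B = f * (1 - Q)``: a fully resolved atom
(Q = 1) gets B = 0, and progressively less-resolved atoms get larger
displacement parameters. The single scaling factor f is chosen by rendering
a model map with the candidate B factors and maximizing its cross-
correlation about the mean (CC-mean) with the experimental map over a scan
of f values (0-300 by default).

Rendering uses the standard isotropic-displacement convention: an atom with
B factor B contributes a normalized Gaussian of variance

    sigma^2 = sigma0^2 + B / (8 pi^2)

where sigma0 is the intrinsic peak width at B = 0 (0.6 A by default, the
reference-profile width of the Q-score). Atoms contribute equal integral
scaled by occupancy; element-specific scattering factors are deliberately
not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AtomicModel, DensityMap
from .qscore import QResult, correlation_about_mean

__all__ = [
    "BFactorFit",
    "q_to_bfactor",
    "grid_for_model",
    "render_model_map",
    "cc_mean",
    "mask_near_atoms",
    "optimize_scale",
]

DEFAULT_SCAN = np.arange(0.0, 300.0 + 1e-9, 10.0)
EIGHT_PI2 = 8.0 * np.pi**2


@dataclass
class BFactorFit:
    """Result of the scaling-factor scan."""

    f_opt: float
    cc_curve: list[tuple[float, float]]  # (f, cc_mean) over the scan grid
    b_atoms: np.ndarray  # per-atom B at f_opt, aligned with model.atoms (NaN: unscored)


def q_to_bfactor(q, f: float):
    """B = f * (1 - Q), clamped at 0 (Pearson Q never exceeds 1)."""
    if f < 0:
        raise ValueError("scaling factor must be non-negative")
    return np.maximum(f * (1.0 - np.asarray(q, dtype=float)), 0.0)


def grid_for_model(
    model: AtomicModel, voxel: float = 0.5, margin: float = 4.0
) -> DensityMap:
    """An empty map whose grid covers the model extent plus a margin."""
    pos = model.positions()
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    return DensityMap(
        values=np.zeros(tuple(shape)),
        voxel_size=np.full(3, float(voxel)),
        origin=lo,
    )


def render_model_map(
    positions: np.ndarray,
    b_atoms: np.ndarray,
    grid: DensityMap,
    occupancies: np.ndarray | None = None,
    sigma0: float = 0.6,
    cutoff_sigmas: float = 4.0,
) -> DensityMap:
    """Render a model map: one isotropic Gaussian per atom, summed.

    Each atom adds ``occ / (2 pi sigma^2)^{3/2} * exp(-r^2 / (2 sigma^2))``
    with ``sigma^2 = sigma0^2 + B/(8 pi^2)``, evaluated out to
    ``cutoff_sigmas`` standard deviations (contributions of atoms near the
    grid edge are truncated at the boundary).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    b_atoms = np.broadcast_to(
        np.asarray(b_atoms, dtype=float), (len(positions),)
    )
    if np.any(b_atoms < 0):
        raise ValueError("B factors must be non-negative")
    if occupancies is None:
        occupancies = np.ones(len(positions))
    values = np.zeros(grid.shape)
    shape = np.array(grid.shape)
    axes_idx = [np.arange(n) for n in shape]
    for pos, b, occ in zip(positions, b_atoms, occupancies):
        sigma2 = sigma0**2 + b / EIGHT_PI2
        sigma = np.sqrt(sigma2)
        cutoff = cutoff_sigmas * sigma
        center_idx = (pos - grid.origin) / grid.voxel_size
        lo = np.maximum(np.floor(center_idx - cutoff / grid.voxel_size).astype(int), 0)
        hi = np.minimum(
            np.ceil(center_idx + cutoff / grid.voxel_size).astype(int) + 1, shape
        )
        if np.any(lo >= hi):
            continue
        # squared distances from the atom along each axis, outer-summed
        dx2 = [
            (grid.origin[a] + axes_idx[a][lo[a] : hi[a]] * grid.voxel_size[a] - pos[a])
            ** 2
            for a in range(3)
        ]
        r2 = (
            dx2[0][:, None, None] + dx2[1][None, :, None] + dx2[2][None, None, :]
        )
        amp = occ / (2.0 * np.pi * sigma2) ** 1.5
        values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(
            -r2 / (2.0 * sigma2)
        )
    return DensityMap(values=values, voxel_size=grid.voxel_size.copy(), origin=grid.origin.copy())


def cc_mean(
    map_a: DensityMap, map_b: DensityMap, mask: np.ndarray | None = None
) -> float:
    """Cross-correlation about the mean between two maps on the same grid."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    a = map_a.values
    b = map_b.values
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask must match the grid shape")
        a = a[mask]
        b = b[mask]
        if a.size < 2:
            raise ValueError("mask leaves fewer than 2 voxels")
    return correlation_about_mean(a.ravel(), b.ravel())


def mask_near_atoms(
    grid: DensityMap, positions: np.ndarray, radius: float = 3.0
) -> np.ndarray:
    """Boolean voxel mask within ``radius`` A of any atom position."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    mask = np.zeros(grid.shape, dtype=bool)
    shape = np.array(grid.shape)
    axes_idx = [np.arange(n) for n in shape]
    r2max = radius**2
    for pos in positions:
        center_idx = (pos - grid.origin) / grid.voxel_size
        lo = np.maximum(np.floor(center_idx - radius / grid.voxel_size).astype(int), 0)
        hi = np.minimum(
            np.ceil(center_idx + radius / grid.voxel_size).astype(int) + 1, shape
        )
        if np.any(lo >= hi):
            continue
        dx2 = [
            (grid.origin[a] + axes_idx[a][lo[a] : hi[a]] * grid.voxel_size[a] - pos[a])
            ** 2
            for a in range(3)
        ]
        r2 = dx2[0][:, None, None] + dx2[1][None, :, None] + dx2[2][None, None, :]
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= r2 <= r2max
    return mask


def optimize_scale(
    dmap: DensityMap,
    model: AtomicModel,
    qresult: QResult,
    scan: np.ndarray | None = None,
    sigma0: float = 0.6,
    mask: str | np.ndarray | None = "model",
    mask_radius: float = 3.0,
) -> BFactorFit:
    """Find the scaling factor f maximizing CC-mean(model map, experimental).

    For each f in the scan grid (0-300 step 10 by default), per-atom B
    factors ``f * (1 - Q)`` are rendered into a model map on the
    experimental grid and compared with the experimental map by CC-mean
    over voxels within ``mask_radius`` of the model (``mask="model"``; pass
    None for whole-grid, or an explicit boolean array). Ties break to the
    smallest f. Only scored atoms are rendered.
    """
    scan = DEFAULT_SCAN if scan is None else np.asarray(scan, dtype=float)
    if scan.size == 0:
        raise ValueError("empty scan grid")
    scored = qresult.scored_mask
    if not scored.any():
        raise ValueError("no scored atoms")
    pos = model.positions()[scored]
    occ = np.array([a.occupancy for a in model.atoms])[scored]
    qs = qresult.q[scored]
    if isinstance(mask, str) and mask == "model":
        mask_arr: np.ndarray | None = mask_near_atoms(dmap, pos, mask_radius)
    else:
        mask_arr = mask  # None or an explicit array
    curve: list[tuple[float, float]] = []
    for f in scan:
        rendered = render_model_map(pos, q_to_bfactor(qs, f), dmap, occ, sigma0=sigma0)
        curve.append((float(f), cc_mean(rendered, dmap, mask_arr)))
    ccs = np.array([c for _, c in curve])
    f_opt = float(scan[int(np.argmax(ccs))])  # first max => smallest f on ties
    b_full = np.full(len(model.atoms), np.nan)
    b_full[scored] = q_to_bfactor(qs, f_opt)
    return BFactorFit(f_opt=f_opt, cc_curve=curve, b_atoms=b_full)
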