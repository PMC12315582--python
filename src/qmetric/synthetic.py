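"""Synthetic fixtures: toy models, rendered maps, and archive tables.

Everything here is desk-scale and seeded. Toy models carry canonical
residue/atom names (so grouping rules apply) with atoms laid out along a
smooth helical space curve at ~1.4 A spacing — chemically labeled
pseudo-atoms, not real stereochemistry. Synthetic archives reproduce the
statistical structure of the real EMDB-wide Q-vs-resolution scatter: a
decreasing cubic mean curve with skewed residuals (long tail toward low Q,
as misfitted models produce) and a unimodal resolution density peaking
near 3-4 A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .bfactor import grid_for_model, render_model_map
from .io import ArchiveTable, AtomicModel, AtomRecord, DensityMap

__all__ = [
    "ArchiveSimSpec",
    "default_mean_curve",
    "make_toy_model",
    "simulate_map",
    "simulate_archive",
]

# anchor points pinning the default synthetic mean curve: Q ~0.95 at 1 A,
# ~0.5 at 3 A (resolved side chains), ~0.3 at 5 A, ~0.1 at 10 A
_ANCHORS_D = np.array([1.0, 3.0, 5.0, 10.0])
_ANCHORS_Q = np.array([0.95, 0.5, 0.3, 0.1])

_EULER_GAMMA = float(np.euler_gamma)

# atom-name templates (canonical names so group classification applies)
_TEMPLATES = {
    "helix": ("ALA", ["N", "CA", "C", "O", "CB"], False),
    "strand": ("SER", ["N", "CA", "C", "O", "CB", "OG"], False),
    "rna": (
        "G",
        [
            "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
            "C2'", "O2'", "C1'", "N9", "C8", "N7", "C5", "C6", "O6", "N1",
            "C2", "N2", "N3", "C4",
        ],
        False,
    ),
    "ligand": (
        "NAG",
        ["C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "N2", "O3", "O4", "O5", "O6", "O7"],
        True,
    ),
}


def default_mean_curve() -> np.ndarray:
    """Ascending cubic coefficients through the default anchor points."""
    return npoly.polyfit(_ANCHORS_D, _ANCHORS_Q, 3)


@dataclass
class ArchiveSimSpec:
    """Conditions for a synthetic archive of (entry, resolution, mean Q) rows.

    n : number of entries.
    d_range : resolution span in A (1-10 by default, like the real archive).
    mean_curve : ascending cubic coefficients of the mean Q(d) curve.
    noise_scale : scale of the residual distribution (Q units).
    noise : ``gumbel`` (mirrored, long lower tail — the skew seen in real
        archives), ``normal``, or ``none``.
    d_beta : (a, b) of the Beta density shaping the resolution distribution
        over d_range; the default peaks near 3.3 A.
    """

    n: int = 10_000
    d_range: tuple[float, float] = (1.0, 10.0)
    mean_curve: np.ndarray = field(default_factory=default_mean_curve)
    noise_scale: float = 0.05
    noise: str = "gumbel"
    d_beta: tuple[float, float] = (2.2, 4.5)
    seed: int = 0


def simulate_archive(spec: ArchiveSimSpec | None = None, **overrides) -> ArchiveTable:
    """Draw a synthetic archive table per the spec (reproducible per seed).

    Each row is ``q = mean_curve(d) + residual``. Generated Q values
    escaping [-0.1, 1.05] trigger a warning (no silent clipping).
    """
    spec = spec or ArchiveSimSpec()
    if overrides:
        spec = ArchiveSimSpec(**{**spec.__dict__, **overrides})
    rng = np.random.default_rng(spec.seed)
    d0, d1 = spec.d_range
    d = d0 + (d1 - d0) * rng.beta(*spec.d_beta, size=spec.n)
    base = npoly.polyval(d, np.asarray(spec.mean_curve, dtype=float))
    if spec.noise == "gumbel":
        # mirrored Gumbel: long tail toward low Q, mean-centered
        g = rng.gumbel(0.0, spec.noise_scale, size=spec.n)
        resid = -(g - _EULER_GAMMA * spec.noise_scale)
    elif spec.noise == "normal":
        resid = rng.normal(0.0, spec.noise_scale, size=spec.n)
    elif spec.noise == "none":
        resid = np.zeros(spec.n)
    else:
        raise ValueError(f"unknown noise kind {spec.noise!r}")
    q = base + resid
    n_out = int(np.count_nonzero((q < -0.1) | (q > 1.05)))
    if n_out:
        warnings.warn(
            f"{n_out} synthetic Q values outside [-0.1, 1.05]; not clipped"
        )
    frame = pd.DataFrame(
        {
            "entry_id": [f"SYN-{i:06d}" for i in range(spec.n)],
            "resolution": d,
            "q": q,
        }
    )
    return ArchiveTable(frame)


def _curve_point(k: float, radius: float = 3.0, omega: float = 0.35, rise: float = 0.9):
    return np.array(
        [radius * np.cos(omega * k), radius * np.sin(omega * k), rise * k]
    )


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from {atom_name!r}")


def make_toy_model(
    n_residues: int, kind: str = "helix", seed: int = 0, chain: str = "A"
) -> AtomicModel:
    """A deterministic toy model with canonical residue and atom names.

    Atoms are placed consecutively along a helical curve at ~1.4 A spacing
    with a small seeded jitter; ``kind`` selects the residue template
    (``helix`` -> ALA, ``strand`` -> SER, ``rna`` -> G nucleotides,
    ``ligand`` -> NAG saccharide units).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if kind not in _TEMPLATES:
        raise ValueError(f"unknown kind {kind!r}; choose from {sorted(_TEMPLATES)}")
    res_name, atom_names, hetero = _TEMPLATES[kind]
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 0
    k = 0.0
    for ri in range(1, n_residues + 1):
        for name in atom_names:
            serial += 1
            pos = _curve_point(k) + rng.normal(0.0, 0.03, size=3)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_element_of(name),
                    chain=chain,
                    res_name=res_name,
                    res_seq=ri,
                    coord=pos,
                    occupancy=1.0,
                    b_iso=0.0,
                    is_hetero=hetero,
                )
            )
            k += 1.0
        k += 0.5  # small gap between residues
    return AtomicModel(atoms=atoms, entry_id=f"toy-{kind}-{n_residues}")


def simulate_map(
    model: AtomicModel,
    b_atoms: np.ndarray | float = 0.0,
    voxel: float = 0.5,
    noise_rms: float = 0.0,
    seed: int = 0,
    margin: float = 4.0,
    sigma0: float = 0.6,
) -> DensityMap:
    """Render the model into a map and add Gaussian white noise.

    ``noise_rms`` is the noise standard deviation as a fraction of the
    noise-free signal RMSD. The true per-atom B values are recorded in the
    map's ``metadata["true_b"]``.
    """
    b_atoms = np.broadcast_to(
        np.asarray(b_atoms, dtype=float), (len(model.atoms),)
    ).copy()
    grid = grid_for_model(model, voxel=voxel, margin=margin)
    occ = np.array([a.occupancy for a in model.atoms])
    rendered = render_model_map(
        model.positions(), b_atoms, grid, occupancies=occ, sigma0=sigma0
    )
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        rendered.values = rendered.values + rng.normal(
            0.0, noise_rms * rendered.rmsd, size=rendered.shape
        )
    rendered.metadata["true_b"] = b_atoms
    rendered.metadata["noise_rms"] = float(noise_rms)
    return rendered
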