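"""Aggregation of per-atom Q-scores into chemically meaningful groups.

Protein residues are split into backbone and side-chain atoms; nucleotides
into phosphate, ribose (sugar) and base atoms; non-polymer components
(ligands, saccharide units, waters) are scored as single units. Group means
are the per-group analogue of the model-level mean Q and plot directly as
per-residue/per-nucleotide resolvability profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import AtomicModel
from .qscore import QResult

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "classify_atom",
    "aggregate",
    "flag_low_groups",
]

AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE
       LEU LYS MET PHE PRO SER THR TRP TYR VAL""".split()
)
NUCLEOTIDES = frozenset("A C G U DA DC DG DT".split())

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O5'"})
# O2' belongs to ribose in RNA and is simply absent in DNA
RIBOSE_ATOMS = frozenset({"C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"})


def classify_atom(res_name: str, atom_name: str, warn_unknown: bool = True) -> str:
    """Group label for one atom.

    Amino acids -> ``backbone`` / ``sidechain``; nucleotides -> ``phosphate``
    / ``ribose`` / ``base``; any other component -> its component name
    (ligand, saccharide, water). Unknown atom names within known polymers
    fall through to the residue-specific catch-all group.
    """
    res_name = res_name.strip().upper()
    atom_name = atom_name.strip().upper().replace("*", "'")
    if res_name in AMINO_ACIDS:
        return "backbone" if atom_name in BACKBONE_ATOMS else "sidechain"
    if res_name in NUCLEOTIDES:
        if atom_name in PHOSPHATE_ATOMS:
            return "phosphate"
        if atom_name in RIBOSE_ATOMS:
            return "ribose"
        return "base"
    if not res_name:
        if warn_unknown:
            warnings.warn("atom with empty residue name classified as 'other'")
        return "other"
    return res_name


def aggregate(
    qresult: QResult, model: AtomicModel, level: str = "auto"
) -> pd.DataFrame:
    """Mean Q per (chain, residue, group).

    ``level`` restricts which residues are emitted: ``residue`` (amino acids
    only), ``nucleotide``, ``component`` (non-polymer), or ``auto`` (all).
    Groups with no scored atom are omitted. Columns: chain, res_seq,
    res_name, group, mean_q, n_atoms.
    """
    if level not in ("auto", "residue", "nucleotide", "component"):
        raise ValueError(f"unknown aggregation level {level!r}")
    if len(qresult.q) != len(model.atoms):
        raise ValueError("QResult is not aligned with the model")
    rows: dict[tuple, list[float]] = {}
    for i, rec in enumerate(model.atoms):
        if not np.isfinite(qresult.q[i]):
            continue
        rn = rec.res_name.strip().upper()
        if level == "residue" and rn not in AMINO_ACIDS:
            continue
        if level == "nucleotide" and rn not in NUCLEOTIDES:
            continue
        if level == "component" and (rn in AMINO_ACIDS or rn in NUCLEOTIDES):
            continue
        group = classify_atom(rec.res_name, rec.name, warn_unknown=False)
        key = (rec.chain, rec.res_seq, rec.res_name, group)
        rows.setdefault(key, []).append(float(qresult.q[i]))
    out = pd.DataFrame(
        [
            {
                "chain": chain,
                "res_seq": res_seq,
                "res_name": res_name,
                "group": group,
                "mean_q": float(np.mean(qs)),
                "n_atoms": len(qs),
            }
            for (chain, res_seq, res_name, group), qs in rows.items()
        ]
    )
    if len(out):
        out = out.sort_values(["chain", "res_seq", "group"]).reset_index(drop=True)
    return out


def flag_low_groups(groups: pd.DataFrame, bundle, d: float) -> pd.DataFrame:
    """Classify each group mean against the archive bounds at resolution d.

    Adds a ``flag`` column with values ``below_low`` / ``typical`` /
    ``above_high`` by comparison to Q_low_95%(d) and Q_high_95%(d).
    """
    from .stats import classify_entry

    out = groups.copy()
    out["flag"] = [
        classify_entry(q, d, bundle) for q in out["mean_q"].to_numpy(dtype=float)
    ]
    return out
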