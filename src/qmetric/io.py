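"""Readers and writers for density maps, atomic models and archive tables.

Density maps are MRC/CCP4 volumes (read through gemmi); atomic models are
PDB or mmCIF; archive tables are delimited text with one row per EMDB entry
(entry id, reported resolution in Angstrom, mean Q-score).

Coordinate convention: all positions are in Angstrom, with the center of
voxel (i, j, k) at ``origin + (i, j, k) * voxel_size`` (0-based indices).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "DensityMap",
    "AtomRecord",
    "AtomicModel",
    "ArchiveTable",
    "MapFormatError",
    "ModelFormatError",
    "ArchiveFormatError",
    "read_density_map",
    "write_density_map",
    "read_model",
    "write_annotated_model",
    "read_archive_csv",
    "write_scores_table",
    "read_scores_table",
    "write_attribute_file",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class MapFormatError(ValueError):
    """Raised when a density-map file cannot be interpreted."""


class ModelFormatError(ValueError):
    """Raised when a coordinate file yields no usable atoms."""


class ArchiveFormatError(ValueError):
    """Raised when an archive table has no parsable rows."""


@dataclass
class DensityMap:
    """A 3D scalar density grid with physical metadata.

    Attributes
    ----------
    values : (nx, ny, nz) float array
        Map values, X fastest-varying axis first.
    voxel_size : (3,) float array
        Angstrom per voxel along each axis; all components > 0.
    origin : (3,) float array
        Angstrom position of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.values.ndim != 3:
            raise MapFormatError("map values must be a 3D array")
        if not np.all(self.voxel_size > 0):
            raise MapFormatError("voxel size components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def rmsd(self) -> float:
        """Standard deviation of map values about the mean."""
        return float(self.values.std())

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Map Angstrom positions to continuous (fractional) voxel indices."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        return (positions - self.origin) / self.voxel_size

    def index_to_position(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + indices * self.voxel_size

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of positions inside the interpolatable grid hull."""
        idx = self.position_to_index(positions)
        upper = np.array(self.shape, dtype=float) - 1.0
        return np.all((idx >= 0.0) & (idx <= upper), axis=1)

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Angstrom positions (must be in-grid)."""
        from scipy.ndimage import map_coordinates

        idx = self.position_to_index(positions)
        return map_coordinates(self.values, idx.T, order=1, mode="nearest")


@dataclass
class AtomRecord:
    """One atom from a coordinate file (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    chain: str
    res_name: str
    res_seq: int
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float | None = None
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)
        if not self.element:
            raise ModelFormatError(f"atom {self.serial} has empty element")
        if not np.all(np.isfinite(self.coord)):
            raise ModelFormatError(f"atom {self.serial} has non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ModelFormatError(
                f"atom {self.serial} occupancy {self.occupancy} outside [0, 1]"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.res_name.upper() in WATER_NAMES


@dataclass
class AtomicModel:
    """An ordered collection of atoms parsed from one coordinate file."""

    atoms: list[AtomRecord]
    entry_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def scorable_indices(self, include_waters: bool = True) -> np.ndarray:
        """Indices of atoms eligible for Q-scoring: non-H, occupancy > 0."""
        keep = [
            i
            for i, a in enumerate(self.atoms)
            if not a.is_hydrogen
            and a.occupancy > 0
            and (include_waters or not a.is_water)
        ]
        return np.asarray(keep, dtype=int)


@dataclass
class ArchiveTable:
    """Rows of (entry_id, resolution d [A], mean Q) for archive statistics."""

    frame: pd.DataFrame  # columns: entry_id, resolution, q
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"entry_id", "resolution", "q"}
        if not required.issubset(self.frame.columns):
            raise ArchiveFormatError(
                f"archive frame must have columns {sorted(required)}"
            )
        if len(self.frame) and not np.all(self.frame["resolution"].to_numpy() > 0):
            raise ArchiveFormatError("archive resolutions must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def d(self) -> np.ndarray:
        return self.frame["resolution"].to_numpy(dtype=float)

    @property
    def q(self) -> np.ndarray:
        return self.frame["q"].to_numpy(dtype=float)

    def restrict(self, d_min: float, d_max: float) -> "ArchiveTable":
        m = (self.d >= d_min) & (self.d <= d_max)
        return ArchiveTable(self.frame[m].reset_index(drop=True), self.n_dropped)


# ---------------------------------------------------------------------------
# Density maps


def read_density_map(path, origin_override: np.ndarray | None = None) -> DensityMap:
    """Read an MRC/CCP4 volume.

    The grid origin resolves the two conventions in the wild: the ORIGIN
    header fields are used when any is nonzero, otherwise the NSTART header
    times the voxel size. ``origin_override`` bypasses both.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc

    values = np.array(ccp4.grid, copy=True, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"map {path} contains non-finite voxels")
    # voxel size from the header directly (cell / sampling): gemmi's
    # grid.spacing is left at 0 for sub-box maps (nonzero NSTART)
    cell = np.array([ccp4.header_float(i) for i in (11, 12, 13)], dtype=float)
    sampling = np.array([ccp4.header_i32(i) for i in (8, 9, 10)], dtype=float)
    if not np.all(cell > 0) or not np.all(sampling > 0):
        raise MapFormatError(f"map {path} has zero voxel size")
    spacing = cell / sampling

    if origin_override is not None:
        origin = np.asarray(origin_override, dtype=float).reshape(3)
    else:
        header_origin = np.array(
            [ccp4.header_float(i) for i in (50, 51, 52)], dtype=float
        )
        if np.any(header_origin != 0.0):
            origin = header_origin
        else:
            nstart = np.array([ccp4.header_i32(i) for i in (5, 6, 7)], dtype=float)
            origin = nstart * spacing
    return DensityMap(values=values, voxel_size=spacing, origin=origin)


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC/CCP4 (mode 2, ORIGIN header carries the origin)."""
    grid = gemmi.FloatGrid(np.asarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.shape
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * dmap.voxel_size[0],
            ny * dmap.voxel_size[1],
            nz * dmap.voxel_size[2],
            90.0,
            90.0,
            90.0,
        )
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Atomic models


def _records_from_structure(st: gemmi.Structure) -> list[AtomRecord]:
    records: list[AtomRecord] = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    serial += 1
                    records.append(
                        AtomRecord(
                            serial=atom.serial if atom.serial else serial,
                            name=atom.name,
                            element=atom.element.name,
                            chain=chain.name,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            occupancy=float(np.clip(atom.occ, 0.0, 1.0)),
                            altloc=atom.altloc.strip("\x00"),
                            b_iso=float(atom.b_iso),
                            is_hetero=res.het_flag == "H",
                        )
                    )
        break  # first model only
    return records


def _resolve_altlocs(records: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy == "all":
        return records
    if policy != "occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")
    best: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        key = (rec.chain, rec.res_seq, rec.res_name, rec.name)
        j = best.get(key)
        # keep highest occupancy; ties resolved to first occurrence in file
        if j is None or rec.occupancy > records[j].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [records[i] for i in keep]


def read_model(path, altloc_policy: str = "occupancy") -> AtomicModel:
    """Read a PDB or mmCIF coordinate file into an :class:`AtomicModel`.

    Hydrogens and waters are retained (flagged on the records); altloc
    duplicates are resolved by ``altloc_policy``: ``"occupancy"`` keeps the
    highest-occupancy conformer (ties: first in file), ``"all"`` keeps all.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"cannot read model {path}: {exc}") from exc
    records = _records_from_structure(st)
    if not records:
        raise ModelFormatError(f"no atoms parsed from {path}")
    records = _resolve_altlocs(records, altloc_policy)
    entry_id = st.name or Path(str(path)).stem
    return AtomicModel(atoms=records, entry_id=entry_id)


def model_to_structure(model: AtomicModel) -> gemmi.Structure:
    """Build a gemmi Structure from an AtomicModel (P1 cell, one model)."""
    st = gemmi.Structure()
    st.name = model.entry_id or "model"
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec in model.atoms:
        if rec.chain not in chains:
            chains[rec.chain] = gemmi.Chain(rec.chain)
        chain = chains[rec.chain]
        if len(chain) == 0 or chain[-1].seqid.num != rec.res_seq or chain[-1].name != rec.res_name:
            res = gemmi.Residue()
            res.name = rec.res_name
            res.seqid = gemmi.SeqId(rec.res_seq, " ")
            res.het_flag = "H" if rec.is_hetero else "A"
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = rec.name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*rec.coord)
        atom.occ = rec.occupancy
        atom.altloc = rec.altloc if rec.altloc else "\x00"
        atom.b_iso = rec.b_iso if rec.b_iso is not None else 0.0
        atom.serial = rec.serial
        res.add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_annotated_model(
    model: AtomicModel, b_factors: dict[int, float] | np.ndarray, path
) -> None:
    """Write the model with the B-factor column replaced.

    ``b_factors`` is either an array aligned with ``model.atoms`` or a mapping
    from atom index to B (Angstrom^2). Atoms without a value get the sentinel
    0.00 and are listed in a ``<path>.unscored.txt`` sidecar so the output
    stays standards-valid.
    """
    n = len(model.atoms)
    if isinstance(b_factors, dict):
        bvals = np.full(n, np.nan)
        for i, b in b_factors.items():
            if not 0 <= i < n:
                raise ValueError(f"atom index {i} out of range")
            bvals[i] = b
    else:
        bvals = np.asarray(b_factors, dtype=float)
        if bvals.shape != (n,):
            raise ValueError(
                f"expected {n} B values, got shape {bvals.shape}"
            )
    unscored = [i for i in range(n) if not np.isfinite(bvals[i])]

    annotated = dataclasses.replace(model)
    annotated.atoms = [
        dataclasses.replace(
            rec, b_iso=float(bvals[i]) if np.isfinite(bvals[i]) else 0.0
        )
        for i, rec in enumerate(model.atoms)
    ]
    st = model_to_structure(annotated)
    path = Path(str(path))
    if path.suffix.lower() == ".cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    if unscored:
        sidecar = path.with_suffix(path.suffix + ".unscored.txt")
        with open(sidecar, "w") as fh:
            for i in unscored:
                rec = model.atoms[i]
                fh.write(f"{rec.chain}\t{rec.res_seq}\t{rec.res_name}\t{rec.name}\n")


# ---------------------------------------------------------------------------
# Archive tables and score tables

_ID_HINTS = ("entry", "emdb", "id")
_RES_HINTS = ("resolution", "res", "d")
_Q_HINTS = ("average_qscore_value", "qscore", "q_mean", "mean_q", "q")


def _find_column(columns, hints) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for hint in hints:
        if hint in lowered:
            return lowered[hint]
    for hint in hints:
        for low, orig in lowered.items():
            if hint in low:
                return orig
    return None


def read_archive_csv(path, sep: str = ",") -> ArchiveTable:
    """Read an archive table (entry id, resolution, mean Q) from delimited text.

    Column names are matched loosely (the EMDB API export header
    ``emdb_id,...,resolution,average_qscore_value`` works as-is); rows with a
    missing resolution or Q are dropped and counted in ``n_dropped``.
    """
    try:
        df = pd.read_csv(path, sep=sep, skipinitialspace=True)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ArchiveFormatError(f"cannot read archive {path}: {exc}") from exc
    id_col = _find_column(df.columns, _ID_HINTS)
    res_col = _find_column(df.columns, _RES_HINTS)
    q_col = _find_column([c for c in df.columns if c != res_col], _Q_HINTS)
    if res_col is None or q_col is None:
        raise ArchiveFormatError(
            f"cannot map columns {list(df.columns)} to (entry id, resolution, Q)"
        )
    out = pd.DataFrame(
        {
            "entry_id": (
                df[id_col].astype(str)
                if id_col is not None
                else [f"row{i}" for i in range(len(df))]
            ),
            "resolution": pd.to_numeric(df[res_col], errors="coerce"),
            "q": pd.to_numeric(df[q_col], errors="coerce"),
        }
    )
    n0 = len(out)
    out = out.dropna(subset=["resolution", "q"]).reset_index(drop=True)
    if len(out) == 0:
        raise ArchiveFormatError(f"no parsable rows in {path}")
    return ArchiveTable(out, n_dropped=n0 - len(out))


def write_scores_table(scores: pd.DataFrame, path) -> None:
    """Write a per-atom or per-group score table as CSV (stable column order)."""
    if len(scores) == 0:
        raise ValueError("refusing to write an empty score table")
    scores.to_csv(path, index=False)


def read_scores_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ArchiveFormatError(f"no rows in score table {path}")
    return df


def write_attribute_file(
    groups: pd.DataFrame, path, attribute: str = "qscore"
) -> None:
    """Write per-residue scores as a visualization attribute file.

    Format: the ``defattr`` convention understood by molecular viewers,
    one line per residue keyed ``/<chain>:<res_seq>``.
    """
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\n")
        fh.write("recipient: residues\n")
        for _, row in groups.iterrows():
            fh.write(f"\t/{row['chain']}:{int(row['res_seq'])}\t{row['mean_q']:.4f}\n")
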