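"""Density-map and Cα-structure I/O.

All downstream geometry lives in world ångström coordinates. A
:class:`DensityGrid` is a regular 3D scalar field with an origin and
per-axis voxel size; voxel index ``(i, j, k)`` (0-based) sits at world
position ``origin + voxel_size * (i, j, k)``. Only orthogonal cells are
supported — the near-atomic single-particle maps this package targets
are all orthogonal, and rejecting skew cells keeps the geometry simple.

MRC/CCP4 reading and writing is delegated to :mod:`gemmi`; any
MAPC/MAPR/MAPS axis permutation in the file is normalized to canonical
X, Y, Z order at read time. The origin is taken from the ORIGIN header
record when it is set, falling back to ``NCSTART * voxel_size`` (the two
MRC dialects found in the wild).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "DensityGrid",
    "CaStructure",
    "MapFormatError",
    "UnsupportedGeometryError",
    "OutOfBoundsError",
    "read_map",
    "write_map",
    "interpolate_density",
    "read_ca_structure",
    "write_ca_model",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class MapFormatError(ValueError):
    """The file is not a valid MRC/CCP4 volume."""


class UnsupportedGeometryError(ValueError):
    """The map's unit cell is not orthogonal."""


class OutOfBoundsError(ValueError):
    """A query point lies outside the grid bounding box."""


@dataclass
class DensityGrid:
    """Regular 3D density field in world Å coordinates.

    Attributes
    ----------
    values:
        3D array indexed ``[i, j, k]`` along X, Y, Z.
    origin:
        World position (Å) of voxel ``(0, 0, 0)``.
    voxel_size:
        Per-axis voxel spacing (Å), all components > 0.
    contour_level:
        Recommended iso-value (map units) that density thresholds are
        expressed against.
    """

    values: np.ndarray
    origin: np.ndarray
    voxel_size: np.ndarray
    contour_level: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with all dims >= 1")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def upper_corner(self) -> np.ndarray:
        """World position of the last voxel center."""
        return self.origin + self.voxel_size * (np.array(self.shape) - 1)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(ijk, dtype=float)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def grid_points(self) -> np.ndarray:
        """World positions of every voxel center, shape (n_voxels, 3)."""
        ii, jj, kk = np.meshgrid(
            *(np.arange(n) for n in self.shape), indexing="ij"
        )
        ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.voxel_to_world(ijk)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = self.origin - 1e-9
        hi = self.upper_corner + 1e-9
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass
class CaStructure:
    """Ordered Cα trace: (1-based residue index, 1-letter code, position Å)."""

    residues: list[tuple[int, str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        for _, aa, _ in self.residues:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown amino-acid code {aa!r}")
        self.residues = [
            (int(i), aa, np.asarray(pos, dtype=float).reshape(3))
            for i, aa, pos in self.residues
        ]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        if not self.residues:
            return np.empty((0, 3))
        return np.stack([pos for _, _, pos in self.residues])

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa, _ in self.residues)

    @property
    def indices(self) -> list[int]:
        return [i for i, _, _ in self.residues]

    @classmethod
    def from_arrays(
        cls,
        coords: np.ndarray,
        sequence: str | None = None,
        start_index: int = 1,
        indices: Sequence[int] | None = None,
    ) -> "CaStructure":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = len(coords)
        if sequence is None:
            sequence = "A" * n
        if indices is None:
            indices = range(start_index, start_index + n)
        return cls([(int(i), aa, c) for i, aa, c in zip(indices, sequence, coords)])


# ---------------------------------------------------------------------------
# MRC/CCP4 maps

def read_map(path: str | Path) -> DensityGrid:
    """Read an MRC/CCP4 volume into a :class:`DensityGrid`.

    Axis permutations (MAPC/MAPR/MAPS ≠ 1,2,3) are normalized so the
    returned array is indexed X, Y, Z. Raises
    :class:`UnsupportedGeometryError` for non-orthogonal cells and
    :class:`MapFormatError` for malformed files.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"not a valid MRC/CCP4 map: {path}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90.0) < 1e-3
        and abs(cell.beta - 90.0) < 1e-3
        and abs(cell.gamma - 90.0) < 1e-3
    ):
        raise UnsupportedGeometryError(
            f"non-orthogonal cell (α,β,γ)=({cell.alpha},{cell.beta},{cell.gamma})"
        )
    # header fields must be read before setup(), which normalizes them
    origin_hdr = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
    axes = [m.header_i32(w) - 1 for w in (17, 18, 19)]  # MAPC/MAPR/MAPS

    # normalizes axis order and expands to the full cell extent
    m.setup(float("nan"))
    values = np.array(m.grid, copy=True)
    nx, ny, nz = values.shape
    voxel_size = np.array([cell.a / nx, cell.b / ny, cell.c / nz])

    if np.any(origin_hdr != 0.0):
        origin = origin_hdr
    else:
        # NSTART is stored in file (fast, medium, slow) slot order
        reordered = np.empty(3)
        for slot, ax in enumerate(axes):
            reordered[ax] = nstart[slot]
        origin = reordered * voxel_size

    contour = _read_contour_label(m)
    return DensityGrid(values, origin, voxel_size, contour_level=contour)


_CONTOUR_LABEL = "catrace contour="


def _read_contour_label(m: gemmi.Ccp4Map) -> float:
    nlabl = m.header_i32(56)
    for i in range(max(0, min(nlabl, 10))):
        lab = m.header_str(57 + i * 20, 80).strip("\x00 ")
        if lab.startswith(_CONTOUR_LABEL):
            try:
                return float(lab[len(_CONTOUR_LABEL):])
            except ValueError:
                pass
    return 0.0


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a :class:`DensityGrid` as an MRC/CCP4 2014 file.

    Values are stored as float32 (MRC mode 2); the origin goes into the
    ORIGIN header record and the contour level into a map label so the
    read→write→read round trip is lossless.
    """
    values = np.ascontiguousarray(grid.values, dtype=np.float32)
    g = gemmi.FloatGrid(values)
    nx, ny, nz = values.shape
    a, b, c = grid.voxel_size * np.array([nx, ny, nz])
    g.set_unit_cell(gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.set_header_i32(56, 1)
    m.set_header_str(57, f"{_CONTOUR_LABEL}{grid.contour_level!r}")
    m.write_ccp4_map(str(path))


def interpolate_density(grid: DensityGrid, point: np.ndarray) -> float | np.ndarray:
    """Trilinear interpolation of the density at world position(s) ``point``.

    Exact at voxel centers and for any affine field. Accepts a single
    3-vector or an (N, 3) array; raises :class:`OutOfBoundsError` if any
    point is outside the grid bounding box.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    inside = grid.contains(pts)
    if not np.all(inside):
        bad = pts[~inside][0]
        raise OutOfBoundsError(f"point {bad} outside grid bounding box")
    frac = grid.world_to_voxel(pts)
    frac = np.clip(frac, 0.0, np.array(grid.shape, dtype=float) - 1.0)
    base = np.minimum(frac.astype(int), np.array(grid.shape) - 2)
    base = np.maximum(base, 0)
    t = frac - base
    v = grid.values
    i, j, k = base[:, 0], base[:, 1], base[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]

    def at(di: int, dj: int, dk: int) -> np.ndarray:
        return v[
            np.minimum(i + di, grid.shape[0] - 1),
            np.minimum(j + dj, grid.shape[1] - 1),
            np.minimum(k + dk, grid.shape[2] - 1),
        ]

    out = (
        at(0, 0, 0) * (1 - tx) * (1 - ty) * (1 - tz)
        + at(1, 0, 0) * tx * (1 - ty) * (1 - tz)
        + at(0, 1, 0) * (1 - tx) * ty * (1 - tz)
        + at(0, 0, 1) * (1 - tx) * (1 - ty) * tz
        + at(1, 1, 0) * tx * ty * (1 - tz)
        + at(1, 0, 1) * tx * (1 - ty) * tz
        + at(0, 1, 1) * (1 - tx) * ty * tz
        + at(1, 1, 1) * tx * ty * tz
    )
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# PDB Cα structures

def read_ca_structure(path: str | Path, chain: str = "A") -> CaStructure:
    """Extract the Cα trace of one chain from a PDB file, in file order.

    Alt-loc duplicates keep the first Cα seen for a residue (with a
    warning); residues with non-standard names are skipped.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise KeyError(f"chain {chain!r} not found in {path}")
    residues: list[tuple[int, str, np.ndarray]] = []
    seen: set[int] = set()
    for res in ch:
        aa = _THREE_TO_ONE.get(res.name)
        if aa is None:
            continue
        ca = res.find_atom("CA", "*")
        if ca is None:
            continue
        seqid = res.seqid.num
        if seqid in seen:
            warnings.warn(
                f"duplicate CA for residue {seqid} in chain {chain}; keeping first"
            )
            continue
        seen.add(seqid)
        residues.append((seqid, aa, np.array([ca.pos.x, ca.pos.y, ca.pos.z])))
    return CaStructure(residues)


def write_ca_model(
    model: "CaStructure",
    path: str | Path,
    chain: str = "A",
    bfactors: Iterable[float] | None = None,
) -> None:
    """Write a Cα trace as standard PDB ATOM records (CA atoms only).

    Occupancy is 1.00; the B-factor column optionally carries a
    per-residue confidence score. Coordinates are written at the PDB's
    3-decimal precision.
    """
    structure = getattr(model, "structure", model)
    bf = list(bfactors) if bfactors is not None else [0.0] * len(structure)
    if len(bf) != len(structure):
        raise ValueError("bfactors length must match the number of residues")
    lines = []
    for serial, ((idx, aa, pos), b) in enumerate(zip(structure.residues, bf), 1):
        res3 = _ONE_TO_THREE[aa]
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3} {chain}{idx:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{b:6.2f}"
            f"           C  "
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
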