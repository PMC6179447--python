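"""Synthetic backbones and simulated density maps.

These fixtures let every tracing stage be exercised end-to-end without
any deposited map or structure. The simulator realizes the same
generative assumption the tracer itself makes: the observed density is a
sum of Gaussian kernels centred on atoms,

    rho(x) = sum_atoms w_a * exp(-1.5 * ||x - atom_a||^2 / sigma_sim^2)

rendered onto a regular grid that covers the structure's bounding box
plus a padding margin. ``sigma_sim`` defaults to half the nominal map
resolution, so a "4 Å map" uses sigma_sim = 2 Å, which makes 3–5 Å
fixtures look like the continuous tubes real near-atomic maps show
along helices. The fixtures deliberately omit noise, CTF, B-factors and
solvent: they validate tracing logic, not microscopy physics.
"""

from __future__ import annotations

import numpy as np

from .map_io import CaStructure, DensityGrid

__all__ = ["make_helix", "make_hairpin", "simulate_map", "DEFAULT_SIGMA_FACTOR"]

# sigma_sim = DEFAULT_SIGMA_FACTOR * nominal resolution
DEFAULT_SIGMA_FACTOR = 0.5

_HELIX_RADIUS = 2.3      # Å, Cα distance from the helix axis
_HELIX_RISE = 1.5        # Å per residue along the axis
_HELIX_TWIST = np.deg2rad(100.0)  # per residue
_CA_SPACING = 3.8        # Å, canonical virtual Cα–Cα bond
_STRAND_GAP = 5.0        # Å between hairpin strands


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(w @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - (trial @ w) * w
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def make_helix(
    n_res: int,
    start: np.ndarray = (0.0, 0.0, 0.0),
    axis: np.ndarray = (0.0, 0.0, 1.0),
    sequence: str | None = None,
) -> CaStructure:
    """Ideal α-helical Cα trace.

    Radius 2.3 Å, rise 1.5 Å/residue, 100° twist/residue about ``axis``
    (which passes through ``start``); consecutive Cα–Cα distances come
    out at ≈3.8 Å. ``sequence`` defaults to poly-alanine.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    u, v, w = _orthonormal_frame(axis)
    start = np.asarray(start, dtype=float)
    t = np.arange(n_res)
    ang = t * _HELIX_TWIST
    coords = (
        start[None, :]
        + np.outer(t * _HELIX_RISE, w)
        + _HELIX_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )
    return CaStructure.from_arrays(coords, sequence)


def make_hairpin(n_res: int, sequence: str | None = None) -> CaStructure:
    """Antiparallel two-strand hairpin Cα trace.

    Two straight strands (Cα spacing 3.8 Å) separated by 5.0 Å, joined
    by a 2-residue turn on a semicircular arc; a chain-reversal topology
    that stresses direction-aware tracing. ``n_res`` must be even, ≥ 6.
    """
    if n_res < 6 or n_res % 2:
        raise ValueError("n_res must be even and >= 6")
    m = (n_res - 2) // 2  # residues per strand
    x_end = (m - 1) * _CA_SPACING
    strand1 = np.stack(
        [np.arange(m) * _CA_SPACING, np.zeros(m), np.zeros(m)], axis=1
    )
    r = _STRAND_GAP / 2.0
    turn = np.array(
        [
            [x_end + r * np.cos(np.deg2rad(-30)), r + r * np.sin(np.deg2rad(-30)), 0.0],
            [x_end + r * np.cos(np.deg2rad(30)), r + r * np.sin(np.deg2rad(30)), 0.0],
        ]
    )
    strand2 = np.stack(
        [
            x_end - np.arange(m) * _CA_SPACING,
            np.full(m, _STRAND_GAP),
            np.zeros(m),
        ],
        axis=1,
    )
    coords = np.concatenate([strand1, turn, strand2])
    return CaStructure.from_arrays(coords, sequence)


def simulate_map(
    structure: CaStructure,
    voxel: float = 1.0,
    sigma_sim: float = 2.0,
    pad: float = 8.0,
    weight_by_volume: bool = False,
) -> DensityGrid:
    """Render a Cα structure as a simulated density map.

    Each voxel value is the sum over atoms of
    ``w * exp(-1.5 ||x - atom||^2 / sigma_sim^2)``, with ``w = 1`` or,
    when ``weight_by_volume`` is set, the residue volume divided by the
    mean residue volume — giving the density contrast along the chain
    that sequence threading keys on. The contour level is set to the
    60th percentile of the nonzero voxel values (an arbitrary but fixed
    convention; every downstream threshold is expressed relative to it).
    """
    if len(structure) == 0:
        raise ValueError("cannot simulate a map from an empty structure")
    if sigma_sim <= 0 or voxel <= 0:
        raise ValueError("sigma_sim and voxel must be > 0")
    coords = structure.coords
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    origin = lo
    voxel_size = np.full(3, float(voxel))

    if weight_by_volume:
        from .seq_threading import ResidueVolumeTable

        table = ResidueVolumeTable.default()
        weights = np.array([table.volume[aa] for aa in structure.sequence])
        weights = weights / weights.mean()
    else:
        weights = np.ones(len(structure))

    values = np.zeros(shape)
    axes = [origin[d] + voxel * np.arange(shape[d]) for d in range(3)]
    # truncate where the kernel drops below 1e-6 of its peak (~3.04 sigma);
    # the omitted 3D tail mass is ~4e-6 of an atom's integral
    cutoff = sigma_sim * np.sqrt(-np.log(1e-6) / 1.5)
    for atom, w in zip(coords, weights):
        sel = []
        for d in range(3):
            idx = np.nonzero(np.abs(axes[d] - atom[d]) <= cutoff)[0]
            if idx.size == 0:
                sel = None
                break
            sel.append(idx)
        if sel is None:
            continue
        dx = axes[0][sel[0]] - atom[0]
        dy = axes[1][sel[1]] - atom[1]
        dz = axes[2][sel[2]] - atom[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        kern = np.exp(-1.5 * d2 / sigma_sim**2)
        kern[d2 > cutoff**2] = 0.0
        values[np.ix_(sel[0], sel[1], sel[2])] += w * kern

    nonzero = values[values > 0]
    contour = float(np.percentile(nonzero, 60.0)) if nonzero.size else 0.0
    return DensityGrid(values, origin, voxel_size, contour_level=contour)
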