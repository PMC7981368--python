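"""Pore-axis geometry: per-point pore radius R, nearest-atom distance D,
outer-surface radius L, and the pore-domain/voltage-sensor crossover scale nu.

For a pore point p on the aligned axis,

    R(p) = min_i ( ||c_i - p|| - vdW_i )   nearest van der Waals surface
    D(p) = min_i   ||c_i - p||             nearest atom center
    L(p) = max_i ( ||c_i - p|| + vdW_i )   farthest van der Waals surface

R(p) may be negative where the axis is sterically occluded (e.g. a closed
activation gate); it is reported as-is, never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import ChannelStructure


class GeometryError(ValueError):
    pass


@dataclass
class PorePoint:
    """A point on the pore axis with its geometry values (Angstrom)."""

    p: np.ndarray
    R: float
    D: float
    L: float
    nu: float | None = None


@dataclass
class PoreAxisSet:
    """Uniformly spaced pore points sorted by z."""

    points: list[PorePoint]
    z_step: float
    z_range: tuple[float, float]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def z(self) -> np.ndarray:
        return np.array([pt.p[2] for pt in self.points])


def _distances(structure: ChannelStructure, p: np.ndarray) -> np.ndarray:
    if structure.n_atoms == 0:
        raise GeometryError("empty structure")
    return np.linalg.norm(structure.coords - np.asarray(p, dtype=float), axis=1)


def geometry_profile(structure: ChannelStructure, p) -> tuple[float, float, float]:
    """Return (R, D, L) at pore point p."""
    d = _distances(structure, p)
    return (
        float(np.min(d - structure.vdw)),
        float(np.min(d)),
        float(np.max(d + structure.vdw)),
    )


def crossover_scale(
    structure: ChannelStructure,
    p,
    *,
    mode: str = "nearest",
    fraction: float = 0.5,
) -> float:
    """Distance from p at which voltage-sensing-domain structure begins.

    ``nearest`` (default): distance to the nearest VSD-labelled atom center.
    ``fraction``: smallest sampled distance at which VSD atoms make up at
    least ``fraction`` of all atoms within that distance.
    """
    is_vsd = structure.domain == "VSD"
    if not np.any(is_vsd):
        raise GeometryError("segment map required: no VSD-labelled atoms")
    d = _distances(structure, p)
    if mode == "nearest":
        return float(np.min(d[is_vsd]))
    if mode == "fraction":
        order = np.argsort(d, kind="stable")
        frac = np.cumsum(is_vsd[order]) / np.arange(1, len(d) + 1)
        hits = np.nonzero(frac >= fraction)[0]
        if len(hits) == 0:
            raise GeometryError(f"VSD fraction never reaches {fraction}")
        return float(d[order][hits[0]])
    raise ValueError(f"unknown crossover mode {mode!r}")


def build_pore_points(
    structure: ChannelStructure,
    z_step: float = 0.5,
    z_range: tuple[float, float] | None = None,
    *,
    with_nu: bool = False,
    nu_mode: str = "nearest",
) -> PoreAxisSet:
    """Evaluate the geometry profile on a uniform z-grid along the axis.

    Without an explicit ``z_range`` the grid covers the open pore lumen:
    the contiguous z-extent around the structure center where R(p) > 0.
    """
    if z_step <= 0:
        raise GeometryError("z_step must be positive")
    zmin_atoms = float(structure.coords[:, 2].min())
    zmax_atoms = float(structure.coords[:, 2].max())

    if z_range is None:
        z_range = _open_lumen_range(structure, z_step, zmin_atoms, zmax_atoms)
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    if z_lo > z_hi:
        raise GeometryError("empty z_range")
    if z_lo < zmin_atoms or z_hi > zmax_atoms:
        warnings.warn("pore-point z_range extends beyond the atom z-extent")

    n = int(np.floor((z_hi - z_lo) / z_step + 1e-9)) + 1
    zs = z_lo + z_step * np.arange(max(n, 1))
    points = []
    for z in zs:
        p = np.array([0.0, 0.0, z])
        R, D, L = geometry_profile(structure, p)
        nu = crossover_scale(structure, p, mode=nu_mode) if with_nu else None
        points.append(PorePoint(p=p, R=R, D=D, L=L, nu=nu))
    if not points:
        raise GeometryError("empty pore-point grid")
    return PoreAxisSet(points=points, z_step=z_step, z_range=(z_lo, z_hi))


def _open_lumen_range(structure, z_step, zmin, zmax) -> tuple[float, float]:
    """Contiguous R>0 band around the structure's z midpoint."""
    zs = np.arange(zmin, zmax + 1e-9, z_step)
    open_mask = np.array([
        geometry_profile(structure, (0.0, 0.0, z))[0] > 0 for z in zs
    ])
    if not open_mask.any():
        raise GeometryError("no open pore lumen found (R <= 0 everywhere)")
    mid = len(zs) // 2
    idx = np.nonzero(open_mask)[0]
    seed = idx[np.argmin(np.abs(idx - mid))]
    lo = hi = seed
    while lo > 0 and open_mask[lo - 1]:
        lo -= 1
    while hi < len(zs) - 1 and open_mask[hi + 1]:
        hi += 1
    return float(zs[lo]), float(zs[hi])


def geometry_table(axis_set: PoreAxisSet):
    """Per-point geometry as a DataFrame (columns p_z, R, D, L, nu)."""
    import pandas as pd

    return pd.DataFrame({
        "p_z": [pt.p[2] for pt in axis_set.points],
        "R": [pt.R for pt in axis_set.points],
        "D": [pt.D for pt in axis_set.points],
        "L": [pt.L for pt in axis_set.points],
        "nu": [pt.nu if pt.nu is not None else np.nan for pt in axis_set.points],
    })
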