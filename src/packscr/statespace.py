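"""Discrete habitat-masked state space of candidate activity centres.

SCR density refers to a finite region: a regular square lattice of points
("the mask") buffering the trap array, each point a candidate activity
centre with an associated cell area of ``(spacing/1000)**2`` km².  Points
classified as non-habitat (towns, water, open plain ...) are excluded so
that density is expressed per unit of usable habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist


@dataclass
class StateSpace:
    """Regular lattice of candidate activity centres with habitat flags."""

    points: np.ndarray  # (P, 2) metres
    habitat: np.ndarray  # (P,) 0/1
    spacing_m: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.habitat = np.asarray(self.habitat, dtype=np.int8)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (P, 2)")
        if len(self.habitat) != len(self.points):
            raise ValueError("habitat flags length must equal number of points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area_per_point_km2(self) -> float:
        return (self.spacing_m / 1000.0) ** 2

    @property
    def total_area_km2(self) -> float:
        """A: total habitat area in km² (habitat points x cell area)."""
        return float(self.habitat.sum()) * self.area_per_point_km2

    def habitat_points(self) -> np.ndarray:
        return self.points[self.habitat.astype(bool)]


def generate_grid(
    trap_coords: np.ndarray, buffer_m: float = 15000.0, spacing_m: float = 666.0
) -> StateSpace:
    """Build an axis-aligned lattice covering the union of discs of radius
    ``buffer_m`` around the traps.

    The lattice is anchored at the trap centroid (the anchor is immaterial
    once spacing is small relative to sigma, and fixing it makes runs
    reproducible).  Every lattice point within ``buffer_m`` of at least one
    trap is included; all returned points are flagged habitat.
    """
    traps = np.atleast_2d(np.asarray(trap_coords, dtype=float))
    if traps.shape[0] < 1:
        raise ValueError("need at least one trap")
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    if buffer_m < 0:
        raise ValueError("buffer must be non-negative")
    if buffer_m == 0:
        warnings.warn(
            "buffer 0: state space degenerates to lattice points coincident "
            "with traps",
            UserWarning,
            stacklevel=2,
        )
    elif buffer_m < spacing_m:
        raise ValueError("buffer smaller than lattice spacing")

    anchor = traps.mean(axis=0)
    lo = traps.min(axis=0) - buffer_m
    hi = traps.max(axis=0) + buffer_m
    ix_lo = int(np.floor((lo[0] - anchor[0]) / spacing_m))
    ix_hi = int(np.ceil((hi[0] - anchor[0]) / spacing_m))
    iy_lo = int(np.floor((lo[1] - anchor[1]) / spacing_m))
    iy_hi = int(np.ceil((hi[1] - anchor[1]) / spacing_m))
    xs = anchor[0] + spacing_m * np.arange(ix_lo, ix_hi + 1)
    ys = anchor[1] + spacing_m * np.arange(iy_lo, iy_hi + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    d, _ = cKDTree(traps).query(pts, k=1)
    tol = max(buffer_m, 1e-9)
    keep = d <= tol
    pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("no state-space points within buffer of traps")
    return StateSpace(points=pts, habitat=np.ones(len(pts), dtype=np.int8),
                      spacing_m=spacing_m)


def apply_mask(space: StateSpace, habitat_flags: np.ndarray) -> StateSpace:
    """Drop non-habitat points and recompute the habitat area."""
    flags = np.asarray(habitat_flags).astype(np.int8)
    if len(flags) != space.n_points:
        raise ValueError(
            f"habitat flags length {len(flags)} != number of points {space.n_points}"
        )
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("habitat flags must be 0/1")
    keep = flags.astype(bool)
    if not keep.any():
        raise ValueError("all points classified non-habitat")
    return StateSpace(points=space.points[keep],
                      habitat=np.ones(keep.sum(), dtype=np.int8),
                      spacing_m=space.spacing_m)


def distance_matrix(space: StateSpace, trap_coords: np.ndarray) -> np.ndarray:
    """Euclidean distances (metres) from every mask point to every trap."""
    traps = np.atleast_2d(np.asarray(trap_coords, dtype=float))
    return cdist(space.points, traps)
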