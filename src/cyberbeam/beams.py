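"""Geometric beam encoding for CyberKnife plans.

A CyberKnife plan is a set of non-coplanar circular-cone ("pencil") beams,
each defined by a source position, an aim point inside the target, a fixed
secondary-collimator diameter and a monitor-unit (MU) weight.  The *beam
matrix* is a purely geometric 3-D encoding of such a plan on the CT grid:
every voxel accumulates the MU-ratio weight of each beam whose cone
contains it,

    value(p) = sum_j  w_j * [p inside cone_j],
    w_j      = MU_j / min{ MU_k : MU_k > 0 },

optionally plus a target term of +1 on target voxels covered by at least
one collimator projection.  The cone half-angle is the small-angle model

    half_angle = arctan((cone / 4) / L_source),

with ``L_source`` the distance from the dummy radioactive source to the
collimator exit (about 400 mm for the CyberKnife treatment head).

The encoding is deliberately free of any physics (no attenuation, no
inverse-square falloff): it captures *where the machine points*, and is
consumed as a network input channel by :mod:`cyberbeam.model`.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .grid import VolumeGrid

__all__ = [
    "Beam",
    "Plan",
    "BeamMatrix",
    "BeamMatrixEncoder",
    "half_angle",
    "beam_weight",
    "beam_weights",
    "voxel_in_cone",
    "encode",
    "encode_brute_force",
    "partition_target",
]

#: Source-to-collimator-exit distance (mm), per the manufacturer's ~40 cm.
DEFAULT_L_SOURCE = 400.0


@dataclass
class Beam:
    """One circular-cone beam.

    Attributes
    ----------
    source : world position (mm) of the dummy radioactive source.
    aim : world position (mm) of the beam-axis endpoint inside the target.
    cone : secondary-collimator diameter (mm).
    mu : monitor units (>= 0; zero-MU beams are retained but undeliverable).
    l_source : source-to-collimator-exit distance (mm).
    """

    source: np.ndarray
    aim: np.ndarray
    cone: float
    mu: float
    l_source: float = DEFAULT_L_SOURCE

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(3)
        self.aim = np.asarray(self.aim, dtype=float).reshape(3)
        self.cone = float(self.cone)
        self.mu = float(self.mu)
        self.l_source = float(self.l_source)
        if self.cone <= 0:
            raise ValueError(f"cone diameter must be > 0, got {self.cone}")
        if self.mu < 0:
            raise ValueError(f"MU must be >= 0, got {self.mu}")
        if self.l_source <= 0:
            raise ValueError(f"l_source must be > 0, got {self.l_source}")
        if np.allclose(self.source, self.aim):
            raise ValueError("beam source and aim point coincide")

    @property
    def deliverable(self) -> bool:
        """True for beams that carry weight (MU > 0)."""
        return self.mu > 0

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from source towards aim."""
        v = self.aim - self.source
        return v / np.linalg.norm(v)


@dataclass
class Plan:
    """An ordered collection of beams with a prescription."""

    beams: List[Beam]
    prescription_dose: float
    fractions: int = 1

    def __post_init__(self) -> None:
        if len(self.beams) < 1:
            raise ValueError("plan must contain at least one beam")
        if self.prescription_dose <= 0:
            raise ValueError("prescription dose must be > 0")
        if self.fractions < 1:
            raise ValueError("fractions must be a positive integer")

    @property
    def n_beams(self) -> int:
        return len(self.beams)

    @property
    def deliverable_beams(self) -> List[Beam]:
        return [b for b in self.beams if b.deliverable]


@dataclass
class BeamMatrix:
    """The encoded plan: unitless nonnegative weights on a grid."""

    grid: VolumeGrid
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.grid.values < 0):
            raise ValueError("beam matrix values must be nonnegative")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def half_angle(beam: Beam) -> float:
    """Cone half-angle in radians: ``arctan((cone/4) / l_source)``."""
    return float(np.arctan((beam.cone / 4.0) / beam.l_source))


def beam_weights(plan: Plan) -> np.ndarray:
    """MU-ratio weights for every beam of the plan.

    ``w_j = MU_j / min(nonzero MUs)``; zero-MU beams get weight 0.  The
    minimum runs over *deliverable* beams only (a minimum over all beams
    would divide by zero whenever any beam is parked).
    """
    mus = np.array([b.mu for b in plan.beams], dtype=float)
    nonzero = mus[mus > 0]
    if nonzero.size == 0:
        raise ValueError("no deliverable beams: all MUs are zero")
    return np.where(mus > 0, mus / nonzero.min(), 0.0)


def beam_weight(beam: Beam, plan: Plan) -> float:
    """Weight of one beam within its plan (see :func:`beam_weights`)."""
    idx = next(i for i, b in enumerate(plan.beams) if b is beam)
    return float(beam_weights(plan)[idx])


def voxel_in_cone(point: np.ndarray, beam: Beam) -> bool:
    """Is a world point inside the beam's (infinite, forward) cone?

    True iff the angle between ``point - source`` and the beam axis is at
    most the cone half-angle *and* the point projects forward along the
    axis.  The forward-half-space restriction excludes the mirror cone
    behind the source and guards points at the source itself.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    v = point - beam.source
    proj = float(v @ beam.axis)
    if proj <= 0.0:
        return False
    # compare cos(angle) >= cos(half_angle) without dividing: proj >= |v| cos(a)
    return proj >= float(np.linalg.norm(v)) * np.cos(half_angle(beam))


def _cone_membership(points: np.ndarray, beam: Beam) -> np.ndarray:
    """Vectorized :func:`voxel_in_cone` over ``(N, 3)`` points.

    Uses the same floating-point formula as the scalar predicate so that
    both paths agree bitwise.
    """
    v = points - beam.source
    proj = v @ beam.axis
    norms = np.sqrt(np.einsum("ij,ij->i", v, v))
    return (proj > 0.0) & (proj >= norms * np.cos(half_angle(beam)))


class BeamMatrixEncoder(BaseEstimator):
    """Stateless transformer: Plan + grid -> beam matrix.

    Parameters
    ----------
    target_term : bool, default True
        Add +1 once to voxels that are both inside the target mask and
        inside at least one beam cone (the normalized collimator
        projection on the target).
    n_threads : int, default 1
        Voxel blocks are distributed over this many threads; the per-beam
        summation order is fixed, so results are bit-identical for any
        thread count.
    """

    def __init__(self, target_term: bool = True, n_threads: int = 1):
        self.target_term = target_term
        self.n_threads = n_threads

    def transform(
        self,
        plan: Plan,
        grid: VolumeGrid,
        target: Optional[np.ndarray] = None,
    ) -> BeamMatrix:
        """Encode ``plan`` on ``grid`` (optionally with a target mask)."""
        weights = beam_weights(plan)
        points = grid.voxel_centers().reshape(-1, 3)
        n = points.shape[0]

        def encode_block(sl: slice) -> np.ndarray:
            pts = points[sl]
            acc = np.zeros(pts.shape[0])
            covered = np.zeros(pts.shape[0], dtype=bool)
            for beam, w in zip(plan.beams, weights):
                inside = _cone_membership(pts, beam)
                acc += w * inside
                if w > 0:
                    covered |= inside
            return np.stack([acc, covered.astype(float)])

        n_threads = max(1, int(self.n_threads))
        block = max(1, -(-n // n_threads))
        slices = [slice(i, min(i + block, n)) for i in range(0, n, block)]
        if n_threads == 1:
            parts = [encode_block(sl) for sl in slices]
        else:
            with ThreadPoolExecutor(max_workers=n_threads) as pool:
                parts = list(pool.map(encode_block, slices))
        stacked = np.concatenate(parts, axis=1)
        values = stacked[0].reshape(grid.shape)
        covered = stacked[1].reshape(grid.shape) > 0

        if self.target_term:
            if target is None or not np.any(target):
                warnings.warn(
                    "target term requested but target mask is empty/missing; skipped",
                    stacklevel=2,
                )
            else:
                values = values + (np.asarray(target, dtype=bool) & covered)

        return BeamMatrix(
            grid=grid.with_values(values),
            provenance={
                "n_beams": plan.n_beams,
                "target_term": bool(self.target_term),
                "weights": weights.tolist(),
            },
        )


def encode(
    plan: Plan,
    grid: VolumeGrid,
    target: Optional[np.ndarray] = None,
    target_term: bool = True,
    n_threads: int = 1,
) -> BeamMatrix:
    """Functional wrapper over :class:`BeamMatrixEncoder`."""
    return BeamMatrixEncoder(target_term=target_term, n_threads=n_threads).transform(
        plan, grid, target
    )


def encode_brute_force(
    plan: Plan,
    grid: VolumeGrid,
    target: Optional[np.ndarray] = None,
    target_term: bool = True,
) -> np.ndarray:
    """Reference encoder: explicit per-voxel / per-beam python loop.

    A deliberately naive implementation (scalar :func:`voxel_in_cone` per
    voxel per beam) kept as a validation oracle for the vectorized
    encoder; only usable on small grids.
    """
    weights = beam_weights(plan)
    out = np.zeros(grid.shape)
    covered = np.zeros(grid.shape, dtype=bool)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                p = grid.indices_to_world(np.array([i, j, k], dtype=float))
                for beam, w in zip(plan.beams, weights):
                    if voxel_in_cone(p, beam):
                        out[i, j, k] += w
                        if w > 0:
                            covered[i, j, k] = True
    if target_term and target is not None and np.any(target):
        out = out + (np.asarray(target, dtype=bool) & covered)
    return out


def partition_target(
    target: np.ndarray,
    grid: VolumeGrid,
    n_beams: int,
    seed: int = 0,
) -> np.ndarray:
    """Split the target into sub-target aim points, one per beam.

    Deterministic farthest-point sampling of the target voxel centers,
    seeded at the voxel nearest the centroid: each subsequent point
    maximizes the minimum distance to those already chosen (ties broken
    by voxel order).  Used for synthetic plans that lack per-beam aim
    points; clinical plans carry their own.

    Returns ``(n_beams, 3)`` world coordinates, all inside the target.
    """
    target = np.asarray(target, dtype=bool)
    if not np.any(target):
        raise ValueError("target mask is empty")
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    ijk = np.argwhere(target).astype(float)
    if n_beams > ijk.shape[0]:
        raise ValueError(
            f"n_beams ({n_beams}) exceeds target voxel count ({ijk.shape[0]})"
        )
    pts = grid.indices_to_world(ijk)
    centroid = pts.mean(axis=0)
    first = int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))
    chosen = [first]
    mindist = np.linalg.norm(pts - pts[first], axis=1)
    while len(chosen) < n_beams:
        nxt = int(np.argmax(mindist))
        chosen.append(nxt)
        mindist = np.minimum(mindist, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]
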