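"""Synthetic phantom cases: CT, structures, rings, plans, analytic dose.

Clinical CyberKnife data (CT series, RTSTRUCT, RTPLAN, RTDOSE) is not
publicly available, so this module generates desk-scale stand-ins with the
same statistical and geometric structure: a homogeneous head-like
ellipsoid phantom with a thin skull shell, a small spherical intracranial
target surrounded by eye/lens/optic-nerve/chiasm/brainstem-like OARs,
halo rings at fixed margins around the target, non-coplanar fixed-cone
beam sets aimed at the target, and a smooth analytic reference dose
concentrated on the beam-cone union.

The analytic dose engine is this package's own toy physics (synthetic; it
is *not* the clinical Ray-tracing engine): per beam, inverse-square
falloff from the source, exponential attenuation along the ray-marched
in-body depth, and a Gaussian penumbra at the cone edge, summed over
beams with the MU-ratio weights and rescaled so the target D95 equals the
prescription.  It defines a smooth, learnable beam-geometry -> dose
mapping for the prediction network to recover.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .beams import Beam, Plan, encode, half_angle, partition_target
from .grid import StructureRole, StructureSet, VolumeGrid

__all__ = [
    "PhantomSpec",
    "OarSpec",
    "RingSpec",
    "DoseEngineParams",
    "CONE_SET",
    "random_phantom_spec",
    "make_phantom",
    "make_rings",
    "make_plan",
    "analytic_dose",
    "make_dataset",
]

#: Fixed CyberKnife secondary-collimator diameters (mm).
CONE_SET = (5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0)

#: HU values used by the phantom.
HU_AIR = -1000.0
HU_SOFT = 0.0
HU_SKULL = 700.0


@dataclass
class OarSpec:
    """An ellipsoidal organ-at-risk: name, center (mm) and semi-axes (mm)."""

    name: str
    center: Tuple[float, float, float]
    semiaxes: Tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Geometry of one synthetic head phantom."""

    shape: Tuple[int, int, int] = (64, 64, 48)
    spacing: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    head_semiaxes: Tuple[float, float, float] = (75.0, 90.0, 62.0)
    target_center: Tuple[float, float, float] = (15.0, 10.0, 8.0)
    target_radius: float = 10.0
    oars: List[OarSpec] = field(default_factory=list)
    skull_fraction: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_radius <= 2 * min(self.spacing):
            raise ValueError("target radius must exceed 2 voxels")
        c = np.asarray(self.target_center)
        a = np.asarray(self.head_semiaxes)
        # strict containment: the whole sphere inside the inner head surface
        if np.sqrt(np.sum((c / (a * (1 - self.skull_fraction))) ** 2)) + self.target_radius / a.min() >= 1.0:
            raise ValueError("target is not strictly inside the head")


@dataclass
class RingSpec:
    """Halo rings around the target: margins ``(inner, outer]`` in mm."""

    margins: Sequence[Tuple[float, float]] = ((0.0, 5.0), (5.0, 10.0))

    def __post_init__(self) -> None:
        prev_outer = 0.0
        for inner, outer in self.margins:
            if not 0 <= inner < outer:
                raise ValueError(f"degenerate ring margins ({inner}, {outer})")
            if inner < prev_outer:
                raise ValueError("rings must be nested and disjoint")
            prev_outer = outer


@dataclass
class DoseEngineParams:
    """Parameters of the analytic (synthetic) dose engine.

    ``mu`` is the linear attenuation coefficient of the homogeneous soft
    tissue (1/mm; ~0.005/mm for a 6 MV beam in water); ``ref_dist`` the
    source distance at which inverse-square weighting is 1 (mm);
    ``sigma`` the Gaussian penumbra scale at the cone edge (mm).
    """

    mu: float = 0.005
    ref_dist: float = 800.0
    sigma: float = 2.0
    prescription: Optional[float] = None  # None -> take the plan's

    def __post_init__(self) -> None:
        if self.mu < 0 or self.sigma < 0:
            raise ValueError("mu and sigma must be >= 0")


def _default_oars(head: np.ndarray) -> List[OarSpec]:
    """Brain-like OAR layout scaled to the head semi-axes (LPS mm)."""
    a, b, c = head
    return [
        OarSpec("Eye_L", (0.42 * a, -0.72 * b, -0.10 * c), (11.0, 11.0, 11.0)),
        OarSpec("Eye_R", (-0.42 * a, -0.72 * b, -0.10 * c), (11.0, 11.0, 11.0)),
        OarSpec("Lens_L", (0.42 * a, -0.84 * b, -0.10 * c), (4.0, 3.0, 4.0)),
        OarSpec("Lens_R", (-0.42 * a, -0.84 * b, -0.10 * c), (4.0, 3.0, 4.0)),
        OarSpec("OpticNerve_L", (0.24 * a, -0.52 * b, -0.08 * c), (12.0, 5.0, 4.0)),
        OarSpec("OpticNerve_R", (-0.24 * a, -0.52 * b, -0.08 * c), (12.0, 5.0, 4.0)),
        OarSpec("Chiasm", (0.0, -0.30 * b, -0.05 * c), (8.0, 5.0, 4.0)),
        OarSpec("Brainstem", (0.0, 0.12 * b, -0.35 * c), (10.0, 12.0, 25.0)),
    ]


def random_phantom_spec(
    seed: int,
    shape: Tuple[int, int, int] = (64, 64, 48),
    spacing: Tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> PhantomSpec:
    """A randomized but valid phantom: jittered head, target and OARs."""
    rng = np.random.default_rng(seed)
    head = np.array([75.0, 90.0, 62.0]) * rng.uniform(0.92, 1.08, 3)
    radius = float(rng.uniform(8.0, 14.0))
    # offset the target superior-lateral, well inside the head
    for _ in range(100):
        center = rng.uniform(-1, 1, 3) * np.array([0.35, 0.35, 0.30]) * head
        try:
            spec = PhantomSpec(
                shape=shape,
                spacing=spacing,
                head_semiaxes=tuple(head),
                target_center=tuple(center),
                target_radius=radius,
                oars=_default_oars(head),
                seed=int(seed),
            )
            return spec
        except ValueError:
            continue
    raise RuntimeError("could not place a valid target")


def _ellipsoid_rho(centers: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    """Normalized ellipsoid radius of each voxel center."""
    return np.sqrt(np.sum(((centers - center) / semiaxes) ** 2, axis=-1))


def make_phantom(spec: PhantomSpec) -> Tuple[VolumeGrid, StructureSet]:
    """Rasterize the phantom CT and its structures (no plan/dose yet).

    The CT is -1000 HU air outside the head, 0 HU homogeneous soft tissue
    inside, and a thin +700 HU skull shell.  Structures are rasterized by
    analytic sphere/ellipsoid membership of the voxel centers.
    Deterministic for a given spec.
    """
    shape = np.array(spec.shape)
    spacing = np.array(spec.spacing, dtype=float)
    origin = -(shape - 1) * spacing / 2.0
    grid = VolumeGrid(np.zeros(spec.shape, dtype=np.float32), origin, spacing)
    centers = grid.voxel_centers()

    head = np.asarray(spec.head_semiaxes, dtype=float)
    rho = _ellipsoid_rho(centers, np.zeros(3), head)
    body = rho <= 1.0
    shell = (rho <= 1.0) & (rho >= 1.0 - spec.skull_fraction)
    ct = np.full(spec.shape, HU_AIR, dtype=np.float32)
    ct[body] = HU_SOFT
    ct[shell] = HU_SKULL
    ctgrid = grid.with_values(ct)

    structures = StructureSet(grid=ctgrid)
    structures.add("Body", body, StructureRole.BODY)
    tc = np.asarray(spec.target_center, dtype=float)
    dist_t = np.linalg.norm(centers - tc, axis=-1)
    target = dist_t <= spec.target_radius
    structures.add("PTV", target, StructureRole.TARGET_PTV)
    structures.add("GTV", dist_t <= 0.8 * spec.target_radius, StructureRole.TARGET_GTV)
    for oar in spec.oars:
        mask = _ellipsoid_rho(centers, np.asarray(oar.center), np.asarray(oar.semiaxes)) <= 1.0
        mask &= body
        if np.any(mask & target):
            warnings.warn(f"OAR {oar.name!r} overlaps the target", stacklevel=2)
        structures.add(oar.name, mask, StructureRole.OAR)
    return ctgrid, structures


def make_rings(
    target: np.ndarray,
    grid: VolumeGrid,
    spec: RingSpec = RingSpec(),
) -> Dict[str, np.ndarray]:
    """Halo rings: shells of Euclidean distance-to-target within margins.

    ``ring_k = {voxels with inner_k < dist(target) <= outer_k}``; the
    rings are disjoint from the target and from each other by
    construction of the distance partition.
    """
    target = np.asarray(target, dtype=bool)
    if not np.any(target):
        raise ValueError("target mask is empty")
    dist = ndimage.distance_transform_edt(~target, sampling=grid.spacing)
    # the EDT runs voxel-center to voxel-center, and the rasterized target
    # boundary sits on average about a quarter voxel inside the continuous
    # surface; shift the distance field accordingly (monotone, so ring
    # disjointness and the distance partition are unaffected)
    dist = np.maximum(dist - 0.25 * float(min(grid.spacing)), 0.0)
    rings = {}
    for i, (inner, outer) in enumerate(spec.margins, start=1):
        rings[f"Ring{i}"] = (dist > inner) & (dist <= outer)
    return rings


def make_plan(
    target: np.ndarray,
    grid: VolumeGrid,
    n_beams: int = 40,
    cone_set: Sequence[float] = CONE_SET,
    seed: int = 0,
    prescription: float = 24.0,
    fractions: int = 3,
    source_dist: float = 800.0,
) -> Plan:
    """A synthetic non-coplanar fixed-cone plan aimed at the target.

    Sources are sampled on a superior hemisphere of radius
    ``source_dist`` about the target centroid (CyberKnife-node-like,
    non-coplanar); aim points come from farthest-point target
    partitioning; cone diameters are drawn from the fixed cone set,
    capped at the target diameter; MUs are integer log-uniform in
    [10, 500].
    """
    rng = np.random.default_rng(seed)
    target = np.asarray(target, dtype=bool)
    ijk = np.argwhere(target).astype(float)
    centroid = grid.indices_to_world(ijk).mean(axis=0)

    n_aims = min(n_beams, ijk.shape[0])
    aims = partition_target(target, grid, n_aims, seed=seed)
    aim_idx = rng.integers(0, n_aims, size=n_beams) if n_beams > n_aims else np.arange(n_beams)

    # equivalent-sphere diameter of the target caps the cone choice
    r_eq = (3 * target.sum() * grid.voxel_volume / (4 * np.pi)) ** (1 / 3)
    allowed = [c for c in cone_set if c <= 2 * r_eq] or [min(cone_set)]

    beams = []
    for j in range(n_beams):
        az = rng.uniform(0, 2 * np.pi)
        cospol = rng.uniform(np.cos(np.deg2rad(75.0)), 1.0)
        sinpol = np.sqrt(1 - cospol**2)
        direction = np.array([sinpol * np.cos(az), sinpol * np.sin(az), cospol])
        source = centroid + source_dist * direction
        mu = int(np.round(np.exp(rng.uniform(np.log(10.0), np.log(500.0)))))
        beams.append(
            Beam(
                source=source,
                aim=aims[aim_idx[j]],
                cone=float(rng.choice(allowed)),
                mu=mu,
            )
        )
    return Plan(beams=beams, prescription_dose=prescription, fractions=fractions)


def _ray_marched_depth(
    points: np.ndarray,
    source: np.ndarray,
    body: np.ndarray,
    grid: VolumeGrid,
    step: float,
) -> np.ndarray:
    """In-body path length (mm) from the source to each point.

    Voxel-stepped ray marching: samples at ``step`` intervals along each
    ray, counting samples whose nearest voxel lies in the body mask.
    Marching starts one grid diagonal before each point, which all rays
    from an external source traverse before reaching any body voxel.
    """
    t = np.linalg.norm(points - source, axis=1)
    u = (points - source) / t[:, None]
    diag = float(np.linalg.norm(np.array(grid.shape) * grid.spacing))
    n_steps = int(np.ceil(diag / step))
    depth = np.zeros(points.shape[0])
    shape = np.array(grid.shape)
    for i in range(n_steps):
        s = t - diag + (i + 0.5) * step
        active = s < t
        if not np.any(active):
            continue
        pos = source + u[active] * s[active, None]
        idx = np.round(grid.world_to_indices(pos)).astype(int)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        hit = np.zeros(idx.shape[0], dtype=bool)
        sel = idx[inb]
        hit[inb] = body[sel[:, 0], sel[:, 1], sel[:, 2]]
        d = np.zeros(points.shape[0])
        d[active] = hit * step
        depth += d
    return depth


def analytic_dose(
    plan: Plan,
    ct: VolumeGrid,
    target: np.ndarray,
    params: DoseEngineParams = DoseEngineParams(),
) -> VolumeGrid:
    """The synthetic reference dose for a plan on a phantom CT.

    Per beam j and in-body voxel p:

        d_j(p) = w_j * (ref_dist / |p - source_j|)^2
                     * exp(-mu * depth_in_body(p))
                     * penumbra(p)

    where ``penumbra`` is 1 inside the cone and falls off as a Gaussian
    of scale ``sigma`` beyond the cone edge (zero past 3 sigma).  The sum
    over beams is rescaled so the target D95 equals the prescription.
    The body is taken as CT > -500 HU.  Deterministic.
    """
    from .metrics import dose_quantile  # local import avoids a cycle

    target = np.asarray(target, dtype=bool)
    body = ct.values > -500.0
    points = ct.voxel_centers().reshape(-1, 3)
    body_flat = body.ravel()
    dose = np.zeros(points.shape[0])
    from .beams import beam_weights

    weights = beam_weights(plan)
    step = float(min(ct.spacing)) / 2.0
    for beam, w in zip(plan.beams, weights):
        if w == 0:
            continue
        v = points - beam.source
        t = np.sqrt(np.einsum("ij,ij->i", v, v))
        proj = v @ beam.axis
        rp = np.sqrt(np.maximum(t**2 - proj**2, 0.0))
        rc = proj * np.tan(half_angle(beam))
        if params.sigma > 0:
            edge = rp - rc
            pen = np.where(
                edge <= 0, 1.0, np.exp(-0.5 * (edge / params.sigma) ** 2)
            )
            pen[edge > 3 * params.sigma] = 0.0
        else:
            pen = (rp <= rc).astype(float)
        sel = body_flat & (proj > 0) & (pen > 0)
        if not np.any(sel):
            continue
        depth = _ray_marched_depth(points[sel], beam.source, body, ct, step)
        dose[sel] += (
            w
            * (params.ref_dist / t[sel]) ** 2
            * np.exp(-params.mu * depth)
            * pen[sel]
        )
    dose = dose.reshape(ct.shape)
    tdose = dose[target]
    if tdose.size == 0 or tdose.max() <= 0:
        raise RuntimeError("target receives zero dose: all beams miss")
    rx = params.prescription if params.prescription is not None else plan.prescription_dose
    d95 = dose_quantile(tdose, 95)
    if d95 <= 0:
        raise RuntimeError("target D95 is zero; cannot normalize to prescription")
    out = (dose * (rx / d95)).astype(np.float32)
    return ct.with_values(out)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _case_checksum(arrays: Dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()[:16]


def make_dataset(
    out_dir,
    n_cases: int,
    split: Tuple[int, int, int],
    seed: int = 0,
    shape: Tuple[int, int, int] = (64, 64, 48),
    spacing: Tuple[float, float, float] = (3.0, 3.0, 3.0),
    n_beams_range: Tuple[int, int] = (30, 60),
    ring_spec: RingSpec = RingSpec(),
    engine: DoseEngineParams = DoseEngineParams(),
    write_dicom: bool = False,
) -> Dict:
    """Generate a reproducible dataset of synthetic cases on disk.

    Each case directory holds the internal bundle (compressed arrays +
    JSON geometry manifest), a ``.ckplan`` sidecar, the encoded beam
    matrix and the halo rings; ``manifest.json`` records per-case seeds,
    checksums and the train/val/test split.  All randomness flows from
    ``seed`` through per-case spawned generators.
    """
    from . import rtio

    if n_cases < sum(split):
        raise ValueError("n_cases must cover the requested split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_cases)]

    labels = (["train"] * split[0] + ["val"] * split[1] + ["test"] * split[2]
              + ["extra"] * (n_cases - sum(split)))
    manifest = {"seed": int(seed), "split": list(split), "cases": []}
    for i, (cs, label) in enumerate(zip(case_seeds, labels)):
        rng = np.random.default_rng(cs)
        spec = random_phantom_spec(int(rng.integers(2**31)), shape=shape, spacing=spacing)
        ctgrid, structures = make_phantom(spec)
        rings = make_rings(structures.target, ctgrid, ring_spec)
        for name, mask in rings.items():
            structures.add(name, mask, StructureRole.RING)
        n_beams = int(rng.integers(n_beams_range[0], n_beams_range[1] + 1))
        rx = float(rng.choice([21.0, 24.0, 30.0, 36.0]))
        plan = make_plan(
            structures.target, ctgrid, n_beams=n_beams,
            seed=int(rng.integers(2**31)), prescription=rx,
        )
        dose = analytic_dose(plan, ctgrid, structures.target, engine)
        bm = encode(plan, ctgrid, structures.target, target_term=True)

        case_dir = out_dir / f"case_{i:03d}"
        bundle = rtio.CaseBundle(ct=ctgrid, structures=structures, plan=plan, dose=dose)
        rtio.save_case_bundle(bundle, case_dir, beam_matrix=bm)
        if write_dicom:
            rtio.export_dicom(bundle, case_dir / "dicom")
        checksum = _case_checksum(
            {"ct": ctgrid.values, "dose": dose.values, "beam": bm.values,
             **{k: v for k, v in structures.masks.items()}}
        )
        manifest["cases"].append(
            {
                "case": case_dir.name,
                "seed": cs,
                "split": label,
                "n_beams": n_beams,
                "prescription": rx,
                "checksum": checksum,
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
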