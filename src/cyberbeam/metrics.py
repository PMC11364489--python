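"""Dose-distribution evaluation: 3-D gamma, DVH metrics, nCI/HI/GI.

The gamma index combines a distance-to-agreement (DTA, mm) and a dose
difference (% of the normalization dose) into a single per-voxel score:

    gamma(p) = min over candidate points q of
               sqrt( (|q - p| / dta)^2 + ((D_eval(q) - D_ref(p)) / tol)^2 )

and a voxel *passes* when gamma <= 1.  Candidates are taken on a sub-voxel
lattice (spacing / ``subdivisions`` per axis) with trilinear interpolation
of the evaluated dose; with ``subdivisions=1`` the search visits exactly
the voxel centers, which is the resolution at which the exhaustive
brute-force oracle operates.

Plan-quality indices follow the standard stereotactic definitions:
``nCI = (TV * V_RI) / TV_RI^2`` (new conformity index), ``HI = D5 / D95``
(homogeneity), ``GI = V(>= 0.5 Rx) / V(>= Rx)`` (gradient).  Undefined
metrics (empty denominators) are reported as ``None``, never as sentinel
numbers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import StructureRole, StructureSet, VolumeGrid

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_passing_rate",
    "gamma_pass_mask",
    "gamma_brute_force_mask",
    "DVHCurve",
    "dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dose_quantile",
    "PlanQualityIndices",
    "plan_quality",
    "dose_difference_report",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma tolerances: ``dta`` mm / ``dose_pct`` % with a low-dose cutoff.

    ``threshold_pct`` excludes voxels whose reference dose is below that
    percentage of the reference maximum (0 = evaluate everything; OARs
    conventionally use 0.5).  ``normalization`` selects the dose that
    ``dose_pct`` refers to: the global reference maximum (``global_max``,
    the community default) or each voxel's own reference dose (``local``).
    """

    dta: float
    dose_pct: float
    threshold_pct: float = 0.0
    normalization: str = "global_max"

    def __post_init__(self) -> None:
        if self.dta <= 0:
            raise ValueError("dta must be > 0")
        if self.dose_pct <= 0:
            raise ValueError("dose_pct must be > 0")
        if not 0 <= self.threshold_pct < 100:
            raise ValueError("threshold_pct must be in [0, 100)")
        if self.normalization not in ("global_max", "local"):
            raise ValueError("normalization must be 'global_max' or 'local'")

    @classmethod
    def parse(cls, text: str, **kwargs) -> "GammaCriteria":
        """Parse ``"3mm/3%"`` or the compact ``"3mm3"`` form."""
        m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*mm\s*/?\s*(\d+(?:\.\d+)?)\s*%?", text.strip())
        if not m:
            raise ValueError(f"cannot parse gamma criteria from {text!r}")
        return cls(dta=float(m.group(1)), dose_pct=float(m.group(2)), **kwargs)

    @property
    def label(self) -> str:
        return f"{self.dta:g}mm/{self.dose_pct:g}%"


@dataclass
class GammaResult:
    """Per-structure gamma outcome.

    ``passing_rate`` is a percentage in [0, 100], or ``None`` when no
    voxel survived masking/thresholding (undefined, not 100).
    """

    structure: str
    passing_rate: Optional[float]
    n_evaluated: int
    criteria: GammaCriteria


def _lattice_offsets(spacing: np.ndarray, dta: float, subdivisions: int) -> Tuple[np.ndarray, np.ndarray]:
    """Integer lattice offsets (units of spacing/subdivisions) within DTA.

    Returns ``(offsets, dist2)`` sorted by distance; offset (0,0,0) first.
    Only offsets with spatial distance <= dta can ever yield gamma <= 1.
    """
    step = spacing / subdivisions
    nmax = np.floor(dta / step).astype(int)
    axes = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    disp = grid * step
    dist2 = np.einsum("ij,ij->i", disp, disp)
    keep = dist2 <= dta * dta + 1e-12
    grid, dist2 = grid[keep], dist2[keep]
    order = np.argsort(dist2, kind="stable")
    return grid[order], dist2[order]


def _dose_tolerance(ref: np.ndarray, criteria: GammaCriteria) -> np.ndarray | float:
    if criteria.normalization == "global_max":
        refmax = float(ref.max())
        if refmax <= 0:
            raise ValueError("reference dose is identically zero; gamma undefined")
        return criteria.dose_pct / 100.0 * refmax
    return criteria.dose_pct / 100.0 * ref


def gamma_pass_mask(
    ref: VolumeGrid,
    evaluated: VolumeGrid,
    mask: np.ndarray,
    criteria: GammaCriteria,
    subdivisions: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-voxel gamma pass/fail over the evaluated voxels.

    Returns ``(passed, included)``: boolean volumes where ``included``
    marks the voxels evaluated (mask minus the low-dose cutoff) and
    ``passed`` the subset with gamma <= 1.

    Candidates are processed in order of increasing spatial distance with
    early exit once every voxel is decided; a voxel passes as soon as any
    candidate scores gamma <= 1 and fails once candidates within the DTA
    are exhausted.
    """
    if not ref.same_geometry(evaluated):
        raise ValueError("reference and evaluated dose grids are not co-registered")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ref.shape:
        raise ValueError("mask shape does not match dose grid")
    refv = ref.values.astype(float)
    evv = evaluated.values.astype(float)
    refmax = float(refv.max())
    if refmax <= 0:
        raise ValueError("reference dose is identically zero; gamma undefined")
    included = mask & (refv >= criteria.threshold_pct / 100.0 * refmax)

    tol = _dose_tolerance(refv, criteria)
    coords = np.argwhere(included)
    n = coords.shape[0]
    passed_list = np.zeros(n, dtype=bool)
    if n:
        ref_d = refv[included]
        tol_d = tol[included] if isinstance(tol, np.ndarray) else np.full(n, tol)
        offsets, dist2 = _lattice_offsets(ref.spacing, criteria.dta, subdivisions)
        undecided = np.arange(n)
        dta2 = criteria.dta**2
        shape = np.array(ref.shape)
        for off, d2 in zip(offsets, dist2):
            if undecided.size == 0:
                break
            spatial = d2 / dta2
            if spatial > 1.0:
                break
            cc = coords[undecided]
            if subdivisions == 1:
                tgt = cc + off
                inb = np.all((tgt >= 0) & (tgt < shape), axis=1)
                dose_e = np.full(undecided.size, np.nan)
                t = tgt[inb]
                dose_e[inb] = evv[t[:, 0], t[:, 1], t[:, 2]]
            else:
                idx = cc.T + (off / subdivisions)[:, None]
                dose_e = ndimage.map_coordinates(
                    evv, idx, order=1, mode="constant", cval=np.nan
                )
            dd = dose_e - ref_d[undecided]
            t_d = tol_d[undecided]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(
                    t_d > 0, (dd / t_d) ** 2, np.where(dd == 0, 0.0, np.inf)
                )
            ok = np.nan_to_num(spatial + term, nan=np.inf) <= 1.0
            passed_list[undecided[ok]] = True
            undecided = undecided[~ok]
    passed = np.zeros(ref.shape, dtype=bool)
    passed[tuple(coords.T)] = passed_list
    return passed, included


def gamma_passing_rate(
    ref: VolumeGrid,
    evaluated: VolumeGrid,
    mask: np.ndarray,
    criteria: GammaCriteria,
    structure: str = "",
    subdivisions: int = 3,
) -> GammaResult:
    """Gamma passing rate (% of evaluated voxels with gamma <= 1)."""
    passed, included = gamma_pass_mask(ref, evaluated, mask, criteria, subdivisions)
    n_eval = int(included.sum())
    rate = None if n_eval == 0 else 100.0 * float(passed.sum()) / n_eval
    return GammaResult(structure=structure, passing_rate=rate, n_evaluated=n_eval, criteria=criteria)


def gamma_map(
    ref: VolumeGrid,
    evaluated: VolumeGrid,
    mask: np.ndarray,
    criteria: GammaCriteria,
    subdivisions: int = 3,
    search_factor: float = 2.0,
) -> np.ndarray:
    """Full gamma values over the evaluated voxels (NaN elsewhere).

    Unlike the pass/fail search, the minimum runs over the whole lattice
    within ``search_factor * dta`` (default twice the DTA), so gamma
    values above 1 are meaningful up to that radius.  Intended for
    analysis and small grids; the passing rate only needs pass/fail.
    """
    if not ref.same_geometry(evaluated):
        raise ValueError("reference and evaluated dose grids are not co-registered")
    mask = np.asarray(mask, dtype=bool)
    refv = ref.values.astype(float)
    evv = evaluated.values.astype(float)
    refmax = float(refv.max())
    if refmax <= 0:
        raise ValueError("reference dose is identically zero; gamma undefined")
    included = mask & (refv >= criteria.threshold_pct / 100.0 * refmax)
    tol = _dose_tolerance(refv, criteria)
    coords = np.argwhere(included)
    out = np.full(ref.shape, np.nan)
    if coords.size == 0:
        return out
    ref_d = refv[included]
    tol_d = tol[included] if isinstance(tol, np.ndarray) else np.full(coords.shape[0], tol)
    offsets, dist2 = _lattice_offsets(
        ref.spacing, search_factor * criteria.dta, subdivisions
    )
    best = np.full(coords.shape[0], np.inf)
    dta2 = criteria.dta**2
    for off, d2 in zip(offsets, dist2):
        idx = coords.T + (off / subdivisions)[:, None]
        dose_e = ndimage.map_coordinates(evv, idx, order=1, mode="constant", cval=np.nan)
        dd = dose_e - ref_d
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(tol_d > 0, (dd / tol_d) ** 2,
                            np.where(dd == 0, 0.0, np.inf))
        g2 = np.nan_to_num(d2 / dta2 + term, nan=np.inf)
        best = np.minimum(best, g2)
    out[tuple(coords.T)] = np.sqrt(best)
    return out


def gamma_brute_force_mask(
    ref: VolumeGrid,
    evaluated: VolumeGrid,
    mask: np.ndarray,
    criteria: GammaCriteria,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exhaustive voxel-resolution gamma oracle.

    For every evaluated voxel, loops over *all* evaluated-dose voxels
    within the DTA search radius (no early exit, no interpolation, no
    candidate ordering) and takes the true minimum gamma.  Independent of
    the optimized implementation; intended for small grids.
    """
    if not ref.same_geometry(evaluated):
        raise ValueError("reference and evaluated dose grids are not co-registered")
    mask = np.asarray(mask, dtype=bool)
    refv = ref.values.astype(float)
    evv = evaluated.values.astype(float)
    refmax = float(refv.max())
    included = mask & (refv >= criteria.threshold_pct / 100.0 * refmax)
    tol = _dose_tolerance(refv, criteria)
    tol_arr = tol if isinstance(tol, np.ndarray) else np.full(ref.shape, tol)

    # window of voxel offsets within the DTA
    reach = np.floor(criteria.dta / ref.spacing).astype(int)
    rng = [np.arange(-r, r + 1) for r in reach]
    window = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1)
    wdist2 = np.sum((window * ref.spacing) ** 2, axis=-1)

    shape = ref.shape
    passed = np.zeros(shape, dtype=bool)
    dta2 = criteria.dta**2
    for i, j, k in np.argwhere(included):
        best = np.inf
        t = tol_arr[i, j, k]
        r = refv[i, j, k]
        for (a, b, c), d2 in zip(window.reshape(-1, 3), wdist2.ravel()):
            if d2 > dta2 + 1e-12:
                continue
            ii, jj, kk = i + a, j + b, k + c
            if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                continue
            dd = evv[ii, jj, kk] - r
            if t > 0:
                g2 = d2 / dta2 + (dd / t) ** 2
            else:
                g2 = d2 / dta2 if dd == 0 else np.inf
            best = min(best, g2)
        passed[i, j, k] = best <= 1.0
    return passed, included


# ---------------------------------------------------------------------------
# DVH and dose statistics
# ---------------------------------------------------------------------------


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``volume_fraction[k]`` is the fraction of structure voxels whose dose
    is >= ``dose_edges[k]``; it starts at 1 at dose 0 and is
    nonincreasing, reaching 0 beyond the structure maximum.
    """

    structure: str
    dose_edges: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if np.any(np.diff(self.dose_edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("volume_fraction must be nonincreasing")


def dvh(dose: VolumeGrid, mask: np.ndarray, bin_width: float = 0.1, structure: str = "") -> DVHCurve:
    """Cumulative DVH of the masked voxel doses."""
    mask = np.asarray(mask, dtype=bool)
    doses = dose.values[mask]
    if doses.size == 0:
        raise ValueError("cannot compute a DVH for an empty structure")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    top = float(doses.max()) + 2 * bin_width
    edges = np.arange(0.0, top, bin_width)
    srt = np.sort(doses)
    # fraction with dose >= edge: count strictly below edge via searchsorted
    below = np.searchsorted(srt, edges, side="left")
    frac = 1.0 - below / doses.size
    return DVHCurve(structure=structure, dose_edges=edges, volume_fraction=frac)


def dose_at_volume(curve: DVHCurve, q: float) -> float:
    """D_q: the dose received by the hottest q % of the structure volume.

    The maximum dose d with volume fraction >= q/100, linearly
    interpolated between bin edges.
    """
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    target = q / 100.0
    frac = curve.volume_fraction
    edges = curve.dose_edges
    idx = np.nonzero(frac >= target)[0]
    k = int(idx[-1])
    if k == len(edges) - 1 or frac[k] == target:
        return float(edges[k])
    span = frac[k] - frac[k + 1]
    return float(edges[k] + (edges[k + 1] - edges[k]) * (frac[k] - target) / span)


def volume_at_dose(curve: DVHCurve, dose: float) -> float:
    """Volume (%) of the structure receiving at least ``dose`` Gy."""
    return 100.0 * float(np.interp(dose, curve.dose_edges, curve.volume_fraction))


def dose_quantile(doses: np.ndarray, q: float) -> float:
    """Exact D_q from raw voxel doses (step-function convention).

    The largest dose d such that at least q % of voxels receive >= d;
    equals the ceil(n*q/100)-th hottest voxel.  Used where metric
    identities must hold to machine precision (HI, difference reports).
    """
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("empty dose sample")
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    k = int(np.ceil(doses.size * q / 100.0))
    return float(np.sort(doses)[::-1][k - 1])


# ---------------------------------------------------------------------------
# Plan-quality indices
# ---------------------------------------------------------------------------


@dataclass
class PlanQualityIndices:
    """nCI / HI / GI; any of them ``None`` when its denominator is empty."""

    nci: Optional[float]
    hi: Optional[float]
    gi: Optional[float]


def plan_quality(dose: VolumeGrid, target: np.ndarray, prescription: float) -> PlanQualityIndices:
    """Conformity, homogeneity and gradient indices of a dose on a target.

    Volumes are voxel counts times the voxel volume; isodose membership
    is ``dose >= level``.  ``nCI = (TV * V_RI) / TV_RI^2`` with TV the
    target volume, V_RI the prescription-isodose volume and TV_RI their
    intersection; ``HI = D5 / D95`` on the target (exact voxel
    quantiles); ``GI = V(>= Rx/2) / V(>= Rx)``.
    """
    target = np.asarray(target, dtype=bool)
    if not np.any(target):
        raise ValueError("target mask is empty")
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    vv = dose.voxel_volume
    d = dose.values
    iso = d >= prescription
    tv = float(target.sum()) * vv
    v_ri = float(iso.sum()) * vv
    tv_ri = float((iso & target).sum()) * vv

    nci = (tv * v_ri) / tv_ri**2 if tv_ri > 0 else None

    tdose = d[target]
    d5 = dose_quantile(tdose, 5)
    d95 = dose_quantile(tdose, 95)
    hi = d5 / d95 if d95 > 0 else None

    v_half = float((d >= 0.5 * prescription).sum()) * vv
    gi = v_half / v_ri if v_ri > 0 else None
    return PlanQualityIndices(nci=nci, hi=hi, gi=gi)


# ---------------------------------------------------------------------------
# Dose-difference report
# ---------------------------------------------------------------------------

_TARGET_ROLES = (StructureRole.TARGET_PTV, StructureRole.TARGET_GTV)


def dose_difference_report(
    ref: VolumeGrid,
    evaluated: VolumeGrid,
    structures: StructureSet,
) -> Tuple[pd.DataFrame, VolumeGrid]:
    """Per-structure absolute dose-difference table plus the |diff| volume.

    Every structure gets |dDmax| and |dDmean|; targets additionally get
    |dD98|, |dD95|, |dD90|, |dD50|.  Structures with empty masks are
    skipped with a warning.
    """
    if not ref.same_geometry(evaluated):
        raise ValueError("dose grids are not co-registered")
    rows = []
    for name, mask in structures.masks.items():
        if not np.any(mask):
            warnings.warn(f"structure {name!r} has an empty mask; skipped", stacklevel=2)
            continue
        role = structures.roles[name]
        r = ref.values[mask]
        e = evaluated.values[mask]
        row: Dict[str, object] = {
            "structure": name,
            "role": role.value,
            "delta_dmax_gy": abs(float(e.max()) - float(r.max())),
            "delta_dmean_gy": abs(float(e.mean()) - float(r.mean())),
        }
        if role in _TARGET_ROLES:
            for q in (98, 95, 90, 50):
                row[f"delta_d{q}_gy"] = abs(dose_quantile(e, q) - dose_quantile(r, q))
        rows.append(row)
    table = pd.DataFrame(rows)
    diff = ref.with_values(np.abs(evaluated.values - ref.values))
    return table, diff
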