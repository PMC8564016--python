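"""Lesion detection and anatomical parameterization on area profiles.

A stenosis is quantified against a *reference* (disease-free) area
profile reconstructed from the healthy stretches of the vessel.  The
instantaneous diameter stenosis is ``DS(s) = 1 - sqrt(A(s)/A_ref(s))``.
A lesion is a maximal interval where DS exceeds a detection threshold,
extended outward to its anatomical shoulders; it is then reduced to the
parameters the analytical pressure-drop model consumes:

* ``A_p``, ``A_s``, ``A_d`` — lumen areas at the proximal end, the
  maximally stenosed throat, and the distal end;
* ``L``, ``L_ps``, ``L_sd`` — total length and the lengths of the
  contracting and expanding tapers bracketing the throat;
* ``alpha``, ``beta`` — flow entrance and exit half-angles, taken as
  ``atan((r_p - r_s)/L_ps)`` and ``atan((r_d - r_s)/L_sd)`` on
  equivalent circular radii (90° for an abrupt step).

The throat is the contiguous region around the minimum with area within
5% of the minimum: a pointwise minimum would give the "maximally
stenosed segment" zero length on any smooth profile, whereas anatomical
throats have finite extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import LesionError
from .tree import Branch
from .units import MM, MM2, radius_from_area

#: detection threshold: the lower bound of an angiographically "mild" lesion
DEFAULT_DS_MIN = 0.25
#: relative area tolerance defining the finite-length throat
THROAT_TOL = 1.05


@dataclass
class Lesion:
    """One parameterized stenosis (SI lengths/areas, angles in degrees)."""

    branch_id: str
    s_prox: float
    s_dist: float
    s_throat_start: float
    s_throat_end: float
    A_p: float
    A_s: float
    A_d: float
    alpha: float
    beta: float
    ds: float

    @property
    def L(self) -> float:
        return self.s_dist - self.s_prox

    @property
    def L_ps(self) -> float:
        return self.s_throat_start - self.s_prox

    @property
    def L_sd(self) -> float:
        return self.s_dist - self.s_throat_end

    @property
    def L_throat(self) -> float:
        return self.s_throat_end - self.s_throat_start

    def validate(self) -> None:
        if not (self.s_prox < self.s_throat_start <= self.s_throat_end < self.s_dist):
            raise LesionError("throat must lie strictly inside the lesion")
        if self.A_s > min(self.A_p, self.A_d) + 1e-15:
            raise LesionError("throat area exceeds an endpoint area")
        if not (0.0 < self.ds < 1.0):
            raise LesionError("ds must be in (0, 1)")
        for ang in (self.alpha, self.beta):
            if not (0.0 <= ang <= 90.0):
                raise LesionError("angles must be within [0, 90] degrees")


@dataclass
class ReferenceProfile:
    """Disease-free area estimate A_ref(s) on the branch grid (SI)."""

    s: np.ndarray
    area_ref: np.ndarray

    def at(self, s) -> np.ndarray:
        return np.interp(s, self.s, self.area_ref)


def smooth_area_profile(branch: Branch, window: float) -> Branch:
    """Moving-median smoothing of the area profile over ``window`` metres.

    The median is robust to segmentation spikes and, for symmetric
    windows, an exact identity wherever the profile is monotone — so it
    does not bias taper slopes.  Endpoint windows are truncated;
    ``window = 0`` is the identity.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    if window == 0:
        return branch
    s, area = branch.s, branch.area
    half = window / 2.0
    out = np.empty_like(area)
    for i in range(s.size):
        m = (s >= s[i] - half) & (s <= s[i] + half)
        out[i] = np.median(area[m])
    return Branch(id=branch.id, parent_id=branch.parent_id,
                  attach_s=branch.attach_s, s=s.copy(), area=out,
                  xyz=branch.xyz, occluded=branch.occluded)


def reference_area(branch: Branch, percentile: float = 60.0) -> ReferenceProfile:
    """Estimate the disease-free area profile of a branch.

    Healthy anchors are the local area maxima exceeding the given
    percentile of the branch's areas, plus both endpoints; the reference
    is a piecewise-linear interpolation between anchors.  On a healthy
    vessel this reproduces the profile; across a lesion it bridges the
    two healthy shoulders.
    """
    if branch.n_points < 2:
        raise LesionError(f"branch {branch.id!r}: too short for a reference")
    area = branch.area
    thresh = np.percentile(area, percentile)
    peaks, _ = find_peaks(area, plateau_size=1)
    anchors = [0] + [int(p) for p in peaks if area[p] >= thresh] + [area.size - 1]
    anchors = sorted(set(anchors))
    ref = np.interp(branch.s, branch.s[anchors], area[anchors])
    return ReferenceProfile(s=branch.s.copy(), area_ref=ref)


def instantaneous_ds(branch: Branch, ref: ReferenceProfile) -> np.ndarray:
    """Pointwise diameter stenosis 1 - sqrt(A/A_ref), clipped at 0."""
    with np.errstate(invalid="ignore"):
        ds = 1.0 - np.sqrt(branch.area / ref.at(branch.s))
    return np.clip(ds, 0.0, 1.0)


#: DS below this is indistinguishable from a healthy lumen
DS_EDGE = 1e-4


def _extend(ds: np.ndarray, i: int, step: int, ds_edge: float = DS_EDGE) -> int:
    """Walk outward from index ``i`` while the lumen is still narrowed.

    Crosses the half-threshold shoulder and keeps going to the
    reference-recovery point where the instantaneous DS effectively
    vanishes; on the healthy reference the clipped DS is exactly zero,
    so the walk stops at the anatomical lesion end."""
    n = ds.size
    while 0 <= i + step < n and ds[i + step] > ds_edge:
        i += step
    if 0 <= i + step < n:   # land on the first healthy sample itself
        i += step
    return i


def detect_lesions(
    branch: Branch,
    ref: ReferenceProfile,
    ds_min: float = DEFAULT_DS_MIN,
    raw: Branch | None = None,
) -> list[tuple[float, float]]:
    """Maximal lesion intervals (s_prox, s_dist), proximal→distal.

    Core intervals are runs with ``DS(s) >= ds_min``; each is extended
    outward past the half-threshold shoulder and on to the point where
    the instantaneous DS effectively vanishes (the reference-recovery
    point), which locates the anatomical ends of smooth tapers.  When
    the profile in ``branch`` has been smoothed, pass the unsmoothed
    profile as ``raw``: cores come from the smoothed profile (robust to
    segmentation spikes) while the shoulder positions are refined on the
    raw one, which the smoothing blurs by up to half a window.
    Overlapping extents are merged.
    """
    if not (0.0 < ds_min < 1.0):
        raise ValueError("ds_min must be in (0, 1)")
    ds = instantaneous_ds(branch, ref)
    ds_shoulder = ds if raw is None else instantaneous_ds(raw, ref)
    core = ds >= ds_min
    if not np.any(core):
        return []
    idx = np.flatnonzero(core)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    extents = []
    for run in runs:
        lo = _extend(ds_shoulder, int(run[0]), -1)
        hi = _extend(ds_shoulder, int(run[-1]), +1)
        extents.append([lo, hi])
    merged = [extents[0]]
    for lo, hi in extents[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(float(branch.s[lo]), float(branch.s[hi])) for lo, hi in merged]


def parameterize_lesion(
    branch: Branch,
    ref: ReferenceProfile,
    extent: tuple[float, float],
    throat_tol: float = THROAT_TOL,
) -> Lesion:
    """Reduce a detected extent to the analytical model's parameters."""
    s_prox, s_dist = extent
    m = (branch.s >= s_prox - 1e-12) & (branch.s <= s_dist + 1e-12)
    if np.count_nonzero(m) < 3:
        raise LesionError("lesion extent covers fewer than 3 grid points")
    s, area = branch.s[m], branch.area[m]
    i_min = int(np.argmin(area))
    a_s = float(area[i_min])
    if a_s <= 0:
        raise LesionError("occluded throat: area model does not apply")
    # contiguous throat around the minimum within tolerance
    lo = i_min
    while lo > 0 and area[lo - 1] <= throat_tol * a_s:
        lo -= 1
    hi = i_min
    while hi < area.size - 1 and area[hi + 1] <= throat_tol * a_s:
        hi += 1
    lo = max(lo, 1)                 # throat strictly inside the lesion
    hi = min(hi, area.size - 2)
    a_p, a_d = float(area[0]), float(area[-1])
    r_p, r_s, r_d = (radius_from_area(a) for a in (a_p, a_s, a_d))
    l_ps = float(s[lo] - s[0])
    l_sd = float(s[-1] - s[hi])
    alpha = 90.0 if l_ps <= 0 else math.degrees(math.atan((r_p - r_s) / l_ps))
    beta = 90.0 if l_sd <= 0 else math.degrees(math.atan((r_d - r_s) / l_sd))
    ds = 1.0 - math.sqrt(a_s / float(ref.at(s[i_min])))
    lesion = Lesion(
        branch_id=branch.id,
        s_prox=float(s[0]), s_dist=float(s[-1]),
        s_throat_start=float(s[lo]), s_throat_end=float(s[hi]),
        A_p=a_p, A_s=min(a_s, a_p, a_d), A_d=a_d,
        alpha=alpha, beta=beta, ds=ds,
    )
    lesion.validate()
    return lesion


def find_lesions(
    branch: Branch,
    window: float = 1.0 * MM,
    ds_min: float = DEFAULT_DS_MIN,
    throat_tol: float = THROAT_TOL,
) -> list[Lesion]:
    """Smooth, build a reference, detect and parameterize in one call."""
    sm = smooth_area_profile(branch, window)
    ref = reference_area(sm)
    return [
        parameterize_lesion(sm, ref, ext, throat_tol=throat_tol)
        for ext in detect_lesions(sm, ref, ds_min=ds_min, raw=branch)
    ]


#: angiographic severity grades, upper-edge exclusive except occlusion
GRADES = ("normal", "minimal", "mild", "moderate", "severe", "occluded")


def grade_stenosis(ds: float) -> str:
    """Angiographic severity grade for a diameter stenosis fraction.

    normal (no narrowing), minimal (<25%), mild (25–49%),
    moderate (50–69%), severe (70–99%), occluded (100%).
    """
    if not (0.0 <= ds <= 1.0):
        raise ValueError("ds must be in [0, 1]")
    if ds == 0.0:
        return "normal"
    if ds < 0.25:
        return "minimal"
    if ds < 0.50:
        return "mild"
    if ds < 0.70:
        return "moderate"
    if ds < 1.0:
        return "severe"
    return "occluded"


def dominant_lesion(lesions: list[Lesion], drops: list[float]) -> Lesion:
    """The lesion with the largest pressure drop (mmHg).

    For multi-lesion vessels the per-vessel anatomy is reported for the
    hemodynamically dominant lesion.  Ties go to the proximal-most
    lesion; the lists are expected proximal→distal.
    """
    if not lesions or len(lesions) != len(drops):
        raise LesionError("need equal-length, non-empty lesion/drop lists")
    return lesions[int(np.argmax(drops))]


LESION_TABLE_COLUMNS = (
    "vessel_id", "branch_id", "s_prox_mm", "s_dist_mm", "A_p_mm2", "A_s_mm2",
    "A_d_mm2", "L_mm", "L_ps_mm", "L_sd_mm", "alpha_deg", "beta_deg", "ds",
)


def lesion_table(lesions: list[Lesion], vessel_id: str = ""):
    """Lesion anatomy CSV table in clinical units (mm, mm², degrees)."""
    import pandas as pd

    if not lesions:
        return pd.DataFrame(columns=list(LESION_TABLE_COLUMNS))
    rows = []
    for les in lesions:
        rows.append({
            "vessel_id": vessel_id,
            "branch_id": les.branch_id,
            "s_prox_mm": les.s_prox / MM,
            "s_dist_mm": les.s_dist / MM,
            "A_p_mm2": les.A_p / MM2,
            "A_s_mm2": les.A_s / MM2,
            "A_d_mm2": les.A_d / MM2,
            "L_mm": les.L / MM,
            "L_ps_mm": les.L_ps / MM,
            "L_sd_mm": les.L_sd / MM,
            "alpha_deg": les.alpha,
            "beta_deg": les.beta,
            "ds": les.ds,
        })
    return pd.DataFrame(rows)
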