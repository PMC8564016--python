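"""Pressure-drop closures and FFR assembly.

The analytical FFR estimate at a point distal to a lesion is

    FFR = 1 − (ΔP1 + ΔP2) / Pa

with ``Pa`` the mean aortic pressure during hyperemia (mean cuff
pressure minus a fixed hyperemia offset, default 6.8 mmHg), ``ΔP2`` the
viscous (Hagen–Poiseuille) drop from the coronary ostium to the lesion's
proximal end, and ``ΔP1`` the drop across the lesion itself.

The lesion is decomposed into three segments, mechanically analogous to
a contracting pipe, a straight pipe, and an expanding pipe:

* contracting taper (length ``L_ps``): viscous taper drop plus a
  gradual-contraction loss ``ζ_c (ρ/2) q² (1/A_s − 1/A_p)²`` with
  ``ζ_c = 0.5 (1 − A_s/A_p)^(3/4) sin α``;
* throat (length ``L − L_ps − L_sd``): Hagen–Poiseuille at ``A_s``;
* expanding taper (length ``L_sd``): viscous taper drop plus a
  Borda–Carnot-type separation loss ``ζ_e (ρ/2) q² (1/A_s − 1/A_d)²``
  with ``ζ_e = min(1, 2.6 sin β)`` (a diffuser rule capped at the
  sudden-expansion value).

All three components are irreversible losses and hence non-negative; the
reversible Bernoulli pressure difference between the lesion ends is
excluded by default (``include_bernoulli_net`` adds it for study).
Everything here computes in SI (Pa); results exposed in report types are
converted to mmHg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import LesionError, OccludedBranchError
from .flow import FlowAssignment, lesion_flow
from .lesions import Lesion
from .tree import Branch, CoronaryTree, TreeLocation, resample_branch
from .units import MLPS, MMHG, PI

log = logging.getLogger(__name__)

#: default FFR floor used when losses exceed the perfusion pressure
FFR_FLOOR = 0.01


@dataclass(frozen=True)
class FluidProperties:
    """Blood viscosity (Pa·s) and density (kg/m³)."""

    mu: float = 3.5e-3
    rho: float = 1060.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")


def mean_aortic_pressure(sbp: float, dbp: float, offset: float = 6.8) -> float:
    """Hyperemic mean aortic pressure (mmHg) from cuff pressures.

    Mean arterial pressure ``dbp + (sbp − dbp)/3`` minus a fixed offset
    accounting for the aortic pressure fall during hyperemia.
    """
    if not (sbp > dbp > 0):
        raise ValueError("require sbp > dbp > 0")
    return dbp + (sbp - dbp) / 3.0 - offset


def poiseuille_drop(q: float, fluid: FluidProperties, length: float, area: float) -> float:
    """Hagen–Poiseuille drop (Pa): 8π μ L q / A²."""
    if area <= 0:
        raise OccludedBranchError("zero lumen area in Poiseuille drop")
    if length < 0:
        raise ValueError("length must be non-negative")
    return 8.0 * PI * fluid.mu * length * q / (area * area)


def taper_viscous_drop(q: float, fluid: FluidProperties,
                       r1: float, r2: float, length: float) -> float:
    """Viscous drop (Pa) over a linear-radius taper from r1 to r2.

    Integrating the Poiseuille density 8μq/(π r(s)^4) over a linear
    radius profile gives I = L/(3(r1−r2)) (1/r2³ − 1/r1³), continuous in
    the straight-tube limit I = L/r⁴.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if length < 0:
        raise ValueError("length must be non-negative")
    if abs(r1 - r2) < 1e-9 * max(r1, r2):
        integral = length / r1**4
    else:
        integral = length / (3.0 * (r1 - r2)) * (1.0 / r2**3 - 1.0 / r1**3)
    return 8.0 * fluid.mu * q / PI * integral


def contraction_loss(q: float, fluid: FluidProperties,
                     a_p: float, a_s: float, alpha: float) -> float:
    """Irreversible entrance loss (Pa) of a gradual contraction.

    ``alpha`` is the flow entrance angle in degrees; an axial entrance
    (alpha = 0) produces no separation and no loss.
    """
    if a_s > a_p:
        raise ValueError("throat area must not exceed proximal area")
    if a_s <= 0:
        raise OccludedBranchError("zero throat area")
    zeta = 0.5 * (1.0 - a_s / a_p) ** 0.75 * math.sin(math.radians(alpha))
    return zeta * 0.5 * fluid.rho * q * q * (1.0 / a_s - 1.0 / a_p) ** 2


def expansion_loss(q: float, fluid: FluidProperties,
                   a_s: float, a_d: float, beta: float) -> float:
    """Irreversible exit loss (Pa) of an expansion (Borda–Carnot form).

    ``beta`` is the flow exit angle in degrees; the diffuser coefficient
    2.6·sin β is capped at 1, the sudden-expansion value.
    """
    if a_s > a_d:
        raise ValueError("throat area must not exceed distal area")
    if a_s <= 0:
        raise OccludedBranchError("zero throat area")
    zeta = min(1.0, 2.6 * math.sin(math.radians(beta)))
    return zeta * 0.5 * fluid.rho * q * q * (1.0 / a_s - 1.0 / a_d) ** 2


@dataclass
class LesionDropBreakdown:
    """Component drops (mmHg) across one lesion: dp1 = dp_ps + dp_ss + dp_sd."""

    dp_ps: float
    dp_ss: float
    dp_sd: float

    @property
    def dp1(self) -> float:
        return self.dp_ps + self.dp_ss + self.dp_sd


def lesion_pressure_drop(
    lesion: Lesion,
    q: float,
    fluid: FluidProperties,
    include_bernoulli_net: bool = False,
) -> LesionDropBreakdown:
    """Three-segment analytical drop across a lesion for flow ``q`` (m³/s)."""
    if q < 0:
        raise ValueError("flow must be non-negative")
    l_throat = lesion.L_throat
    if l_throat < -1e-12:
        raise LesionError("degenerate lesion: negative throat length")
    from .units import radius_from_area

    r_p, r_s, r_d = (radius_from_area(a) for a in (lesion.A_p, lesion.A_s, lesion.A_d))
    dp_ps = taper_viscous_drop(q, fluid, r_p, r_s, lesion.L_ps) + contraction_loss(
        q, fluid, lesion.A_p, lesion.A_s, lesion.alpha
    )
    dp_ss = poiseuille_drop(q, fluid, max(l_throat, 0.0), lesion.A_s)
    dp_sd = taper_viscous_drop(q, fluid, r_s, r_d, lesion.L_sd) + expansion_loss(
        q, fluid, lesion.A_s, lesion.A_d, lesion.beta
    )
    if include_bernoulli_net:
        dp_sd += 0.5 * fluid.rho * q * q * (1.0 / lesion.A_d**2 - 1.0 / lesion.A_p**2)
    return LesionDropBreakdown(dp_ps=dp_ps / MMHG, dp_ss=dp_ss / MMHG,
                               dp_sd=dp_sd / MMHG)


def _viscous_density(branch: Branch, bf, mu: float,
                     exclude: list[tuple[float, float]]) -> np.ndarray:
    """Pointwise Poiseuille density 8πμ q(s)/A(s)² (Pa/m), zeroed inside
    the excluded intervals (their drop is charged analytically)."""
    if branch.is_occluded:
        raise OccludedBranchError(f"branch {branch.id!r} is occluded")
    q_si = np.array([bf.at(s) for s in branch.s]) * MLPS
    dens = 8.0 * PI * mu * q_si / branch.area**2
    for s0, s1 in exclude:
        # strict interior: boundary samples keep their density so the
        # integral up to a lesion's proximal end stays exact
        dens[(branch.s > s0 + 1e-12) & (branch.s < s1 - 1e-12)] = 0.0
    return dens


def upstream_drop(
    tree: CoronaryTree,
    flows: FlowAssignment,
    lesion: Lesion,
    fluid: FluidProperties,
    all_lesions: list[Lesion] | None = None,
    hyperemic: bool = True,
) -> float:
    """ΔP2 (mmHg): viscous drop from the ostium to the lesion's proximal end.

    Each path segment uses its own branch flow; lesion intervals on the
    path (this lesion's and any other's) are excluded since they are
    charged as ΔP1.
    """
    all_lesions = all_lesions if all_lesions is not None else [lesion]
    path = tree.path_to(TreeLocation(lesion.branch_id, lesion.s_prox))
    table = flows.q_hyper if (hyperemic and flows.q_hyper) else flows.q_rest
    total = 0.0
    for branch, (s0, s1) in path:
        if s1 <= s0:
            continue
        exclude = [
            (l.s_prox, l.s_dist) for l in all_lesions if l.branch_id == branch.id
        ]
        raw = _viscous_density(branch, table[branch.id], fluid.mu, [])
        dens = raw.copy()
        for e0, e1 in exclude:
            dens[(branch.s > e0 + 1e-12) & (branch.s < e1 - 1e-12)] = 0.0
        m = (branch.s > s0 + 1e-12) & (branch.s < s1 - 1e-12)
        # interval ends need not be grid points: add them explicitly,
        # interpolating on the unmasked density (the ends themselves lie
        # outside any excluded lesion)
        s_nodes = np.concatenate(([s0], branch.s[m], [s1]))
        d_nodes = np.concatenate((
            [np.interp(s0, branch.s, raw)], dens[m],
            [np.interp(s1, branch.s, raw)],
        ))
        total += float(np.trapezoid(d_nodes, s_nodes))
    return total / MMHG


def _lesion_cum_drop(s: np.ndarray, lesion: Lesion,
                     bd: LesionDropBreakdown) -> np.ndarray:
    """Cumulative lesion drop (Pa) at grid points: linear ramps over the
    contracting, throat and expanding segments."""

    def ramp(a: float, b: float, val: float) -> np.ndarray:
        if b <= a:
            return np.where(s >= a, val, 0.0)
        return np.clip((s - a) / (b - a), 0.0, 1.0) * val

    return (
        ramp(lesion.s_prox, lesion.s_throat_start, bd.dp_ps * MMHG)
        + ramp(lesion.s_throat_start, lesion.s_throat_end, bd.dp_ss * MMHG)
        + ramp(lesion.s_throat_end, lesion.s_dist, bd.dp_sd * MMHG)
    )


@dataclass
class LesionReport:
    """Per-lesion hemodynamics: flow, drop components, ΔP2, distal FFR."""

    lesion: Lesion
    q_ml_s: float
    breakdown: LesionDropBreakdown
    dp2: float
    ffr_distal: float
    ischemic: bool


@dataclass
class FfrProfile:
    """Cumulative pressure drop and FFR at every centerline point."""

    pa: float                       # mmHg
    s: dict[str, np.ndarray]        # per-branch arc length (m)
    dp_cum: dict[str, np.ndarray]   # per-branch cumulative drop (mmHg)
    ffr: dict[str, np.ndarray]
    lesion_reports: list[LesionReport] = field(default_factory=list)
    clamped: bool = False

    def at(self, loc: TreeLocation) -> float:
        """Linearly interpolated FFR at a tree location."""
        s = self.s[loc.branch_id]
        if not (s[0] - 1e-12 <= loc.s <= s[-1] + 1e-12):
            raise LesionError(f"location outside branch {loc.branch_id!r}")
        return float(np.interp(loc.s, s, self.ffr[loc.branch_id]))

    def to_frame(self, tree: CoronaryTree, flows: FlowAssignment):
        import pandas as pd
        from .units import MM, MM2

        rows = []
        for bid, s in self.s.items():
            b = tree.branches[bid]
            for i in range(s.size):
                rows.append((
                    bid, s[i] / MM, b.area[i] / MM2,
                    flows.flow_at(bid, s[i]),
                    self.dp_cum[bid][i], self.ffr[bid][i],
                ))
        return pd.DataFrame(rows, columns=[
            "branch_id", "s_mm", "area_mm2", "q_ml_s", "dp_cum_mmHg", "ffr",
        ])


def classify_ischemic(ffr: float, threshold: float = 0.80) -> bool:
    """Ischemia call: FFR at or below the threshold (default 0.80)."""
    if not (0.0 < ffr <= 1.0):
        raise ValueError("ffr must be in (0, 1]")
    return ffr <= threshold


def ffr_profile(
    tree: CoronaryTree,
    flows: FlowAssignment,
    lesions: list[Lesion],
    pa: float,
    fluid: FluidProperties,
    ischemia_threshold: float = 0.80,
    ffr_floor: float = FFR_FLOOR,
    include_bernoulli_net: bool = False,
    hyperemic: bool = True,
) -> FfrProfile:
    """Assemble cumulative drops and FFR along every path from the ostium.

    Outside lesions the drop accumulates the pointwise Poiseuille
    density; inside a lesion the analytical three-segment drop is laid
    down as monotone ramps.  FFR is ``1 − ΔP_cum/Pa``, clamped at
    ``ffr_floor`` with a warning if losses reach the perfusion pressure
    (occlusive lesions are outside the model's validity).
    """
    if pa <= 0:
        raise ValueError("pa must be positive")
    by_branch: dict[str, list[Lesion]] = {}
    for les in lesions:
        by_branch.setdefault(les.branch_id, []).append(les)
    table = flows.q_hyper if (hyperemic and flows.q_hyper) else flows.q_rest
    pa_si = pa * MMHG
    prof = FfrProfile(pa=pa, s={}, dp_cum={}, ffr={})
    breakdowns: dict[int, LesionDropBreakdown] = {}

    def visit(branch: Branch, dp0: float) -> None:
        own = by_branch.get(branch.id, [])
        exclude = [(l.s_prox, l.s_dist) for l in own]
        dens = _viscous_density(branch, table[branch.id], fluid.mu, exclude)
        dp = dp0 + cumulative_trapezoid(dens, branch.s, initial=0.0)
        for les in own:
            q_si = lesion_flow(flows, les, hyperemic=hyperemic) * MLPS
            bd = lesion_pressure_drop(les, q_si, fluid, include_bernoulli_net)
            breakdowns[id(les)] = bd
            dp = dp + _lesion_cum_drop(branch.s, les, bd)
        ffr = 1.0 - dp / pa_si
        if np.any(ffr < ffr_floor):
            prof.clamped = True
            log.warning(
                "branch %s: cumulative drop reaches Pa; FFR clamped at %.2f",
                branch.id, ffr_floor,
            )
            ffr = np.maximum(ffr, ffr_floor)
        prof.s[branch.id] = branch.s.copy()
        prof.dp_cum[branch.id] = dp / MMHG
        prof.ffr[branch.id] = ffr
        for child in tree.children(branch.id):
            visit(child, float(np.interp(child.attach_s, branch.s, dp)))

    visit(tree.root, 0.0)
    for les in lesions:
        bd = breakdowns[id(les)]
        dp2 = upstream_drop(tree, flows, les, fluid,
                            all_lesions=lesions, hyperemic=hyperemic)
        ffr_d = prof.at(TreeLocation(les.branch_id, les.s_dist))
        prof.lesion_reports.append(LesionReport(
            lesion=les,
            q_ml_s=lesion_flow(flows, les, hyperemic=hyperemic),
            breakdown=bd, dp2=dp2, ffr_distal=ffr_d,
            ischemic=classify_ischemic(ffr_d, ischemia_threshold),
        ))
    return prof


def ffr_at(profile: FfrProfile, loc: TreeLocation) -> float:
    """FFR at a location (linear interpolation on the profile grid)."""
    return profile.at(loc)


def oracle_pressure_drop(
    branch: Branch,
    lesions: list[Lesion],
    q: float,
    fluid: FluidProperties,
    grid_step: float,
) -> float:
    """Independent numeric drop (mmHg) over a single branch at flow ``q``.

    Re-integrates the same physical closure from the raw geometry: the
    pointwise Poiseuille density 8πμq/A(s)² by Simpson quadrature on a
    fine uniform grid, plus the two algebraic loss terms evaluated from
    each lesion's endpoint areas and angles.  Used only for verification.
    """
    from scipy.integrate import simpson

    fine = resample_branch(branch, grid_step)
    dens = 8.0 * PI * fluid.mu * q / fine.area**2
    total = float(simpson(dens, x=fine.s))
    for les in lesions:
        total += contraction_loss(q, fluid, les.A_p, les.A_s, les.alpha)
        total += expansion_loss(q, fluid, les.A_s, les.A_d, les.beta)
    return total / MMHG
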