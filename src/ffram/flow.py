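"""Coronary flow model: LV-mass-scaled total flow, scaling-law allocation
over the tree, and the stenosis-dependent hyperemic multiplier.

Total resting coronary flow is taken as linear in left-ventricular mass,
``Q_total = q0 · LVM`` with a resting perfusion constant ``q0`` (default
0.8 mL·min⁻¹·g⁻¹, standard resting myocardial perfusion).  At every
bifurcation the flow entering the junction splits among the daughters in
proportion to a power of their *reference healthy* diameters (default
exponent 7/3, the flow–diameter scaling law for coronary bifurcations;
Murray's exponent 3 is a config away).  The reference diameter is a 75th
percentile of equivalent diameters over the daughter's proximal 5 mm, so
a stenosis sitting at a daughter ostium does not starve its own subtree —
a feedback the analytical model must not create.

Hyperemia (pharmacologic vasodilation) multiplies resting flow by a
factor ``k`` that shrinks as the diameter stenosis of the supplying path
grows: a tight stenosis exhausts part of the vasodilatory reserve.  ``k``
is piecewise linear: ``k_max`` up to ``ds_lo``, falling linearly to
``k_floor`` at ``ds_hi``.  Flows are carried per branch as piecewise
constants between junctions, in mL/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import OccludedBranchError
from .tree import Branch, CoronaryTree
from .units import MM

#: default flow–diameter scaling exponent at bifurcations
DEFAULT_EXPONENT = 7.0 / 3.0


@dataclass(frozen=True)
class HyperemiaParams:
    """Piecewise-linear hyperemic multiplier k(ds)."""

    k_max: float = 4.0
    ds_lo: float = 0.3
    ds_hi: float = 0.9
    k_floor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k_max >= self.k_floor >= 1.0):
            raise ValueError("require k_max >= k_floor >= 1")
        if not (0.0 <= self.ds_lo < self.ds_hi <= 1.0):
            raise ValueError("require 0 <= ds_lo < ds_hi <= 1")


@dataclass
class PatientContext:
    """Scalar physiology driving the flow and pressure models.

    Parameters
    ----------
    lvm : float
        Left-ventricular mass (g); scales total resting coronary flow.
    sbp, dbp : float
        Systolic/diastolic cuff pressure (mmHg).
    hct : float, optional
        Hematocrit (fraction); only used when ``use_hct_viscosity``.
    q0 : float
        Resting flow per gram of myocardium (mL·min⁻¹·g⁻¹).
    mu : float
        Blood dynamic viscosity (Pa·s).
    rho : float
        Blood density (kg·m⁻³).
    """

    lvm: float
    sbp: float
    dbp: float
    hct: float | None = None
    q0: float = 0.8
    mu: float = 3.5e-3
    rho: float = 1060.0
    use_hct_viscosity: bool = False
    hyperemia: HyperemiaParams = field(default_factory=HyperemiaParams)

    def __post_init__(self) -> None:
        if self.lvm <= 0:
            raise ValueError("lvm must be positive")
        if not (self.sbp > self.dbp > 0):
            raise ValueError("require sbp > dbp > 0")
        if self.q0 <= 0 or self.mu <= 0 or self.rho <= 0:
            raise ValueError("q0, mu and rho must be positive")
        if self.hct is not None and not (0.0 < self.hct < 1.0):
            raise ValueError("hct must be a fraction in (0, 1)")

    @property
    def viscosity(self) -> float:
        """Effective viscosity (Pa·s), optionally hematocrit-adjusted."""
        if self.use_hct_viscosity and self.hct is not None:
            return 1.2e-3 * math.exp(2.0 * self.hct)
        return self.mu


def total_resting_flow(ctx: PatientContext) -> float:
    """Total resting coronary flow (mL/s): q0 [mL/min/g] · LVM [g] / 60."""
    return ctx.q0 * ctx.lvm / 60.0


def hyperemic_multiplier(ds: float, params: HyperemiaParams = HyperemiaParams()) -> float:
    """Flow-increase factor at maximal hyperemia for a path of severity ``ds``."""
    if not (0.0 <= ds <= 1.0):
        raise ValueError("ds must be in [0, 1]")
    if ds <= params.ds_lo:
        return params.k_max
    if ds >= params.ds_hi:
        return params.k_floor
    frac = (ds - params.ds_lo) / (params.ds_hi - params.ds_lo)
    return params.k_max + (params.k_floor - params.k_max) * frac


@dataclass
class BranchFlow:
    """Piecewise-constant flow along one branch (mL/s).

    ``breaks`` are junction arc lengths (m); segment ``i`` spans
    ``(breaks[i-1], breaks[i])`` with flow ``q[i]``; ``q[0]`` is the
    branch inflow and ``q[-1]`` the distal outflow.
    """

    breaks: np.ndarray
    q: np.ndarray

    def at(self, s: float) -> float:
        """Flow (mL/s) in the segment containing arc length ``s``.

        Exactly at a junction the pre-junction flow is returned, so
        integrals up to a junction use the flow that actually traversed
        the segment."""
        return float(self.q[int(np.searchsorted(self.breaks, s, side="left"))])


@dataclass
class FlowAssignment:
    """Per-branch resting and (optionally) hyperemic flows."""

    q_rest: dict[str, BranchFlow]
    q_hyper: dict[str, BranchFlow] | None = None

    def flow_at(self, branch_id: str, s: float, hyperemic: bool = True) -> float:
        table = self.q_hyper if (hyperemic and self.q_hyper is not None) else self.q_rest
        return table[branch_id].at(s)

    def to_frame(self):
        """Flow report (branch_id, q_rest_ml_s, q_hyper_ml_s) at branch inflow."""
        import pandas as pd

        rows = []
        for bid, bf in self.q_rest.items():
            qh = self.q_hyper[bid].q[0] if self.q_hyper else np.nan
            rows.append((bid, float(bf.q[0]), float(qh)))
        return pd.DataFrame(rows, columns=["branch_id", "q_rest_ml_s", "q_hyper_ml_s"])


_END_TOL = 1e-9  # m; a junction this close to the branch end leaves no distal stub


def _reference_diameter(branch: Branch, s_start: float,
                        window: float = 5.0 * MM, pct: float = 75.0) -> float:
    """Robust healthy diameter (m) over ``window`` of arc starting at ``s_start``."""
    mask = (branch.s >= s_start - 1e-12) & (branch.s <= s_start + window)
    if not np.any(mask):
        mask = np.zeros_like(branch.s, dtype=bool)
        mask[np.argmin(np.abs(branch.s - s_start))] = True
    d = 2.0 * branch.radius[mask]
    return float(np.percentile(d, pct))


def _junctions(tree: CoronaryTree, branch: Branch) -> list[tuple[float, list[Branch]]]:
    groups: dict[float, list[Branch]] = {}
    for child in tree.children(branch.id):
        groups.setdefault(float(child.attach_s), []).append(child)
    return sorted(groups.items())


def allocate_branch_flows(
    tree: CoronaryTree,
    q_total: float,
    exponent: float = DEFAULT_EXPONENT,
    window: float = 5.0 * MM,
) -> FlowAssignment:
    """Distribute ``q_total`` (mL/s) over the tree by the scaling law.

    Conservation is exact by construction: at every junction the incoming
    flow is split into shares that sum to it (daughters weighted by
    reference diameter to the ``exponent``; the parent's distal
    continuation, when it has remaining length, weighted by its own
    distal reference diameter).
    """
    if q_total <= 0:
        raise ValueError("q_total must be positive")
    flows: dict[str, BranchFlow] = {}

    def visit(branch: Branch, q_in: float) -> None:
        if branch.is_occluded:
            raise OccludedBranchError(f"branch {branch.id!r} is occluded")
        breaks, segq = [], [q_in]
        q_cur = q_in
        child_q: list[tuple[Branch, float]] = []
        for s_j, kids in _junctions(tree, branch):
            weights = [
                _reference_diameter(k, k.s[0], window) ** exponent for k in kids
            ]
            has_stub = (branch.s[-1] - s_j) > _END_TOL
            w_cont = (
                _reference_diameter(branch, s_j, window) ** exponent
                if has_stub else 0.0
            )
            total_w = sum(weights) + w_cont
            for k, w in zip(kids, weights):
                child_q.append((k, q_cur * w / total_w))
            q_cur = q_cur * w_cont / total_w
            breaks.append(s_j)
            segq.append(q_cur)
        flows[branch.id] = BranchFlow(breaks=np.array(breaks), q=np.array(segq))
        for k, q in child_q:
            visit(k, q)

    visit(tree.root, float(q_total))
    return FlowAssignment(q_rest=flows)


def outlet_flows(tree: CoronaryTree, table: dict[str, BranchFlow]) -> dict[str, float]:
    """Flow (mL/s) leaving the distal end of each branch (0 if none)."""
    return {bid: float(bf.q[-1]) for bid, bf in table.items()}


def hyperemic_flows(
    tree: CoronaryTree,
    assignment: FlowAssignment,
    lesions_by_branch: dict[str, list],
    params: HyperemiaParams = HyperemiaParams(),
) -> FlowAssignment:
    """Scale terminal flows by k(max path ds) and re-sum junctions exactly.

    For each distal outlet, ``k`` is evaluated at the maximum diameter
    stenosis encountered anywhere on its supply path from the ostium
    (serial lesions: the tightest one governs the reserve).  Internal
    branch flows are then rebuilt by summation from the leaves so that
    conservation holds to round-off.
    """
    rest = assignment.q_rest
    hyper: dict[str, BranchFlow] = {}

    def visit(branch: Branch, ds_in: float) -> float:
        """Build hyperemic flow for ``branch``; return its inflow (mL/s)."""
        own = sorted(lesions_by_branch.get(branch.id, []), key=lambda l: l.s_prox)

        def ds_at(s: float) -> float:
            ds = ds_in
            for les in own:
                if les.s_prox <= s + 1e-12:
                    ds = max(ds, les.ds)
            return ds

        bf = rest[branch.id]
        juncs = _junctions(tree, branch)
        # distal outlet of this branch
        q_out = float(bf.q[-1])
        q_cur = hyperemic_multiplier(ds_at(branch.s[-1]), params) * q_out
        segq = [q_cur]
        for s_j, kids in reversed(juncs):
            q_cur = q_cur + sum(visit(k, ds_at(s_j)) for k in kids)
            segq.append(q_cur)
        segq.reverse()
        hyper[branch.id] = BranchFlow(breaks=bf.breaks.copy(), q=np.array(segq))
        return q_cur

    visit(tree.root, 0.0)
    return FlowAssignment(q_rest=rest, q_hyper=hyper)


def lesion_flow(assignment: FlowAssignment, lesion, hyperemic: bool = True) -> float:
    """Hyperemic (or resting) flow (mL/s) through a lesion's throat."""
    s_mid = 0.5 * (lesion.s_throat_start + lesion.s_throat_end)
    return assignment.flow_at(lesion.branch_id, s_mid, hyperemic=hyperemic)


def junction_residuals(tree: CoronaryTree, table: dict[str, BranchFlow]) -> float:
    """Largest relative conservation violation over all junctions."""
    worst = 0.0
    for branch in tree:
        bf = table[branch.id]
        for i, s_j in enumerate(bf.breaks):
            kids = [
                c for c in tree.children(branch.id)
                if abs(float(c.attach_s) - float(s_j)) < 1e-12
            ]
            inflow = float(bf.q[i])
            outflow = float(bf.q[i + 1]) + sum(table[c.id].q[0] for c in kids)
            if inflow > 0:
                worst = max(worst, abs(inflow - outflow) / inflow)
    return worst
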