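"""Synthetic stenosed vessels, bifurcating trees and virtual cohorts.

Every downstream stage of the pipeline is testable without patient data:
this module generates idealized geometry whose ground truth is known by
construction.  Arguments are in clinical units (mm); the returned trees
are SI like everything else in the library.

A generated stenosis follows the three-segment anatomy used by the
analytical pressure-drop model: a contracting taper of length ``L_ps``,
a flat maximally-stenosed throat, and an expanding taper of length
``L_sd``, embedded in an otherwise healthy vessel of constant reference
radius.  The default taper is a half-cosine in radius (C¹ smooth), which
exercises lesion detection on a non-trivial profile; a linear-radius
taper is available because the tapered-tube viscous closed form is exact
for it, which the numeric-oracle tests exploit.

Virtual cohorts draw anatomical parameters from truncated normals whose
means and spreads match a typical invasively-studied coronary-disease
cohort (throat area ≈ 3.8 ± 2.2 mm², lesion length ≈ 10.8 ± 6.7 mm,
tapers ≈ 3.5–3.7 ± 3 mm, LV mass 115 ± 31 g, cuff pressures 134/77).
They are a desk-scale stand-in for such a cohort, not a reproduction of
any particular one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .flow import PatientContext
from .tree import Branch, CoronaryTree
from .units import MM, area_from_radius


@dataclass
class StenosisSpec:
    """Ground-truth description of one idealized stenosis.

    All lengths in mm; ``ds_true`` is the target diameter stenosis
    (fraction of reference diameter lost at the throat).
    """

    ds_true: float
    L: float = 10.8
    L_ps: float = 3.7
    L_sd: float = 3.5
    center_s: float = 20.0
    reference_radius: float = 1.5
    vessel_length: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ds_true < 1.0):
            raise ValueError("ds_true must be in [0, 1)")
        if self.L_ps + self.L_sd > self.L + 1e-9:
            raise ValueError("L_ps + L_sd must not exceed L")
        if min(self.L, self.L_ps, self.L_sd) < 0:
            raise ValueError("lengths must be non-negative")
        if self.reference_radius <= 0 or self.vessel_length <= 0:
            raise ValueError("radius and vessel length must be positive")
        if self.s_prox < -1e-9 or self.s_dist > self.vessel_length + 1e-9:
            raise ValueError("lesion extends beyond the vessel")

    @property
    def s_prox(self) -> float:
        return self.center_s - self.L / 2.0

    @property
    def s_dist(self) -> float:
        return self.center_s + self.L / 2.0

    @property
    def throat_radius(self) -> float:
        return self.reference_radius * (1.0 - self.ds_true)


@dataclass
class CohortSpec:
    """Sampling plan for a virtual cohort of single-vessel patients."""

    n: int
    prevalence: float = 0.43
    seed: int = 0
    #: (mean, sd, lower, upper) for each sampled quantity
    distributions: dict = field(
        default_factory=lambda: {
            "A_p_mm2": (6.80, 3.66, 2.5, 18.0),
            "L_mm": (10.77, 6.74, 4.0, 30.0),
            "L_ps_mm": (3.71, 3.24, 0.75, 10.0),
            "L_sd_mm": (3.51, 2.79, 0.75, 10.0),
            "lvm_g": (115.0, 31.0, 55.0, 220.0),
            "sbp_mmHg": (134.0, 17.0, 95.0, 200.0),
            "dbp_mmHg": (77.0, 11.0, 50.0, 110.0),
            "hct": (0.419, 0.034, 0.30, 0.55),
            "ds_positive": (0.62, 0.10, 0.50, 0.90),
            "ds_negative": (0.30, 0.13, 0.02, 0.4999),
        }
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        for key, val in self.distributions.items():
            mean, sd, lo, hi = val
            if sd <= 0 or hi <= lo:
                raise ValueError(f"invalid distribution for {key!r}")


def make_straight_tube(
    length: float, radius: float, step: float = 0.5, branch_id: str = "root"
) -> CoronaryTree:
    """Single-branch tree of constant area pi*radius^2 (arguments in mm)."""
    if min(length, radius, step) <= 0:
        raise ValueError("length, radius and step must be positive")
    n = max(1, math.ceil(length / step))
    s = np.linspace(0.0, length, n + 1) * MM
    area = np.full_like(s, area_from_radius(radius * MM))
    b = Branch(id=branch_id, parent_id=None, attach_s=None, s=s, area=area)
    tree = CoronaryTree(branches={branch_id: b}, root_id=branch_id)
    tree.validate()
    return tree


def _radius_profile(spec: StenosisSpec, s_mm: np.ndarray, taper: str) -> np.ndarray:
    r_ref, r_th = spec.reference_radius, spec.throat_radius
    t0, t1 = spec.s_prox + spec.L_ps, spec.s_dist - spec.L_sd
    r = np.full_like(s_mm, r_ref)
    if spec.ds_true == 0.0:
        return r
    if taper == "cosine":
        # half-cosine in radius: zero slope at both ends of each taper
        m = (s_mm >= spec.s_prox) & (s_mm < t0)
        if spec.L_ps > 0:
            u = (s_mm[m] - spec.s_prox) / spec.L_ps
            r[m] = r_ref - (r_ref - r_th) * 0.5 * (1 - np.cos(np.pi * u))
        m = (s_mm > t1) & (s_mm <= spec.s_dist)
        if spec.L_sd > 0:
            u = (spec.s_dist - s_mm[m]) / spec.L_sd
            r[m] = r_ref - (r_ref - r_th) * 0.5 * (1 - np.cos(np.pi * u))
    elif taper == "linear":
        m = (s_mm >= spec.s_prox) & (s_mm < t0)
        if spec.L_ps > 0:
            u = (s_mm[m] - spec.s_prox) / spec.L_ps
            r[m] = r_ref + (r_th - r_ref) * u
        m = (s_mm > t1) & (s_mm <= spec.s_dist)
        if spec.L_sd > 0:
            u = (spec.s_dist - s_mm[m]) / spec.L_sd
            r[m] = r_ref + (r_th - r_ref) * u
    else:
        raise ValueError(f"unknown taper {taper!r}")
    r[(s_mm >= t0) & (s_mm <= t1)] = r_th
    return r


def make_stenosed_vessel(
    spec: StenosisSpec,
    step: float = 0.25,
    taper: str = "cosine",
    branch_id: str = "root",
) -> CoronaryTree:
    """Single-vessel tree realizing ``spec`` exactly at the grid points.

    The lesion's four breakpoints (proximal end, throat start/end, distal
    end) are inserted into the uniform grid so the realized minimum area
    matches ``(1 - ds_true)² · A_ref`` exactly and taper endpoints are
    sampled exactly.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.linspace(0.0, spec.vessel_length,
                       max(1, math.ceil(spec.vessel_length / step)) + 1)
    breaks = [spec.s_prox, spec.s_prox + spec.L_ps,
              spec.s_dist - spec.L_sd, spec.s_dist]
    grid = np.unique(np.concatenate([grid, np.array(breaks)]))
    # drop grid points closer than step/4 to an inserted breakpoint,
    # keeping the breakpoints themselves
    keep = np.ones(grid.size, dtype=bool)
    for b in breaks:
        close = np.abs(grid - b) < step / 4.0
        close &= np.abs(grid - b) > 1e-12
        keep &= ~close
    grid = grid[keep]
    r = _radius_profile(spec, grid, taper)
    branch = Branch(
        id=branch_id, parent_id=None, attach_s=None,
        s=grid * MM, area=area_from_radius(r * MM),
    )
    tree = CoronaryTree(branches={branch_id: branch}, root_id=branch_id)
    tree.validate()
    return tree


def make_bifurcating_tree(
    generations: int,
    root_radius: float = 2.0,
    child_ratios: tuple[float, float] | float = (0.8, 0.8),
    step: float = 0.5,
    length_per_radius: float = 12.0,
) -> CoronaryTree:
    """Binary tree; each child's radius is its parent's times the stated ratio.

    ``generations=1`` is a single branch.  Branch length scales with the
    branch radius (``length_per_radius`` diameters per radius unit keeps
    proportions vessel-like).  Children attach at the distal end of the
    parent, so every junction is a clean bifurcation.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if isinstance(child_ratios, (int, float)):
        child_ratios = (float(child_ratios), float(child_ratios))
    branches: dict[str, Branch] = {}

    def build(bid: str, parent: str | None, attach: float | None,
              radius: float, gen: int) -> None:
        length = length_per_radius * radius
        n = max(1, math.ceil(length / step))
        s = np.linspace(0.0, length, n + 1) * MM
        area = np.full_like(s, area_from_radius(radius * MM))
        branches[bid] = Branch(id=bid, parent_id=parent, attach_s=attach,
                               s=s, area=area)
        if gen < generations:
            for tag, ratio in zip(("a", "b"), child_ratios):
                build(f"{bid}.{tag}", bid, float(s[-1]), radius * ratio, gen + 1)

    build("root", None, None, root_radius, 1)
    tree = CoronaryTree(branches=branches, root_id="root")
    tree.validate()
    return tree


def _draw(rng, dist) -> float:
    mean, sd, lo, hi = dist
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def make_virtual_cohort(
    spec: CohortSpec, step: float = 0.25, taper: str = "cosine"
) -> list[tuple[CoronaryTree, PatientContext, StenosisSpec]]:
    """Draw a reproducible cohort of single-vessel virtual patients.

    Each vessel uses an RNG substream keyed by ``(seed, index)`` so
    growing ``n`` never reshuffles earlier vessels.  A vessel is
    "positive" (ds_true >= 0.5) with probability ``prevalence``.
    """
    out = []
    d = spec.distributions
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        positive = rng.random() < spec.prevalence
        ds = _draw(rng, d["ds_positive" if positive else "ds_negative"])
        a_p = _draw(rng, d["A_p_mm2"])
        r_ref = math.sqrt(a_p / math.pi)
        L = _draw(rng, d["L_mm"])
        l_ps = _draw(rng, d["L_ps_mm"])
        l_sd = _draw(rng, d["L_sd_mm"])
        # keep a finite throat: tapers may not fill more than 90% of L
        scale = 0.9 * L / (l_ps + l_sd)
        if scale < 1.0:
            l_ps *= scale
            l_sd *= scale
        vessel_length = L + 30.0
        sten = StenosisSpec(
            ds_true=ds, L=L, L_ps=l_ps, L_sd=l_sd,
            center_s=vessel_length / 2.0, reference_radius=r_ref,
            vessel_length=vessel_length,
        )
        sbp = _draw(rng, d["sbp_mmHg"])
        dbp = min(_draw(rng, d["dbp_mmHg"]), sbp - 20.0)
        # A single vessel supplies one myocardial territory, not the whole
        # LV: its territory mass follows caliber-flow adaptation (Murray's
        # cube law) against a nominal 4.5 mm root caliber.
        territory = min(1.0, (2.0 * r_ref / 4.5) ** 3)
        ctx = PatientContext(
            lvm=territory * _draw(rng, d["lvm_g"]), sbp=sbp, dbp=dbp,
            hct=_draw(rng, d["hct"]),
        )
        tree = make_stenosed_vessel(sten, step=step, taper=taper)
        out.append((tree, ctx, sten))
    return out
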