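"""Coronary-tree domain model, CTREE-JSON I/O, resampling and topology queries.

A coronary tree is a rooted collection of branches.  Each branch is an
arc-length-parameterized centerline carrying a lumen cross-sectional area
profile; a child branch attaches to its parent at a stated arc length.
Arc length is zero-based at each branch origin, the way straightened
curved-multiplanar vessel exports describe a vessel.  Lumen *area* is the
stored primitive (the quantity segmented from CT cross-sections); the
equivalent circular radius ``sqrt(A/pi)`` is derived where needed.

All in-memory quantities are SI (metres, square metres).  The on-disk
CTREE-JSON dialect uses clinical units (mm, mm²)::

    {"format": "ctree-json/1", "root_id": "...",
     "branches": [{"id": "...", "parent_id": null, "attach_s_mm": null,
                   "points": [{"s_mm": 0.0, "area_mm2": 7.07, ...}]}],
     "meta": {}}

A fully occluded branch (100% diameter stenosis) is encoded as zero area
with an ``occluded`` flag; flow and pressure routines reject such branches
with :class:`~ffram.errors.OccludedBranchError` instead of dividing by zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import TreeFormatError, TreeLookupError, TreeValidationError
from .units import MM, MM2, radius_from_area

FORMAT_TAG = "ctree-json/1"


@dataclass(frozen=True)
class TreeLocation:
    """A point on the tree: branch id plus arc length (m) on that branch."""

    branch_id: str
    s: float


@dataclass
class Branch:
    """One centerline segment with its lumen-area profile.

    Parameters
    ----------
    id : str
        Branch identifier, unique within the tree.
    parent_id : str or None
        Parent branch, ``None`` for the root (ostium) branch.
    attach_s : float or None
        Arc length on the parent (m) where this branch originates.
    s : ndarray
        Arc length samples (m), strictly increasing, ``s[0] >= 0``.
    area : ndarray
        Lumen cross-sectional area (m²) at each sample.
    xyz : ndarray, optional
        Optional ``(n, 3)`` centerline coordinates (m).
    occluded : bool
        Marks a branch whose lumen is fully obstructed (area may be 0).
    """

    id: str
    parent_id: str | None
    attach_s: float | None
    s: np.ndarray
    area: np.ndarray
    xyz: np.ndarray | None = None
    occluded: bool = False

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.xyz is not None:
            self.xyz = np.asarray(self.xyz, dtype=float)

    @property
    def n_points(self) -> int:
        return self.s.size

    @property
    def length(self) -> float:
        """Total arc length of the branch (m)."""
        return float(self.s[-1] - self.s[0])

    @property
    def radius(self) -> np.ndarray:
        """Equivalent circular radius profile (m)."""
        return radius_from_area(self.area)

    @property
    def is_occluded(self) -> bool:
        return self.occluded or bool(np.any(self.area <= 0.0))

    def validate(self) -> None:
        bid = self.id
        if self.s.size < 2:
            raise TreeValidationError(f"branch {bid!r}: fewer than 2 points")
        if not np.all(np.isfinite(self.s)) or not np.all(np.isfinite(self.area)):
            raise TreeValidationError(f"branch {bid!r}: non-finite s or area")
        if self.s[0] < 0:
            raise TreeValidationError(f"branch {bid!r}: negative arc length")
        if np.any(np.diff(self.s) <= 0):
            raise TreeValidationError(
                f"branch {bid!r}: arc length not strictly increasing"
            )
        if self.occluded:
            if np.any(self.area < 0):
                raise TreeValidationError(f"branch {bid!r}: negative area")
        elif np.any(self.area <= 0):
            raise TreeValidationError(
                f"branch {bid!r}: non-positive area on a branch not "
                "flagged occluded"
            )
        if self.xyz is not None and self.xyz.shape != (self.s.size, 3):
            raise TreeValidationError(f"branch {bid!r}: xyz shape mismatch")


@dataclass
class CoronaryTree:
    """Rooted collection of branches with parent/child topology."""

    branches: dict[str, Branch]
    root_id: str
    meta: dict = field(default_factory=dict)

    @property
    def root(self) -> Branch:
        return self.branches[self.root_id]

    def __iter__(self):
        return iter(self.branches.values())

    def branch(self, branch_id: str) -> Branch:
        try:
            return self.branches[branch_id]
        except KeyError:
            raise TreeLookupError(f"unknown branch id {branch_id!r}") from None

    def children(self, branch_id: str) -> list[Branch]:
        """Child branches ordered proximal→distal by attachment point."""
        kids = [b for b in self.branches.values() if b.parent_id == branch_id]
        kids.sort(key=lambda b: (b.attach_s, b.id))
        return kids

    def validate(self) -> None:
        if self.root_id not in self.branches:
            raise TreeValidationError(f"root id {self.root_id!r} not among branches")
        roots = [b for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise TreeValidationError(
                "tree must have exactly one root branch matching root_id"
            )
        for b in self.branches.values():
            b.validate()
            if b.parent_id is None:
                continue
            if b.parent_id not in self.branches:
                raise TreeValidationError(
                    f"branch {b.id!r}: dangling parent_id {b.parent_id!r}"
                )
            parent = self.branches[b.parent_id]
            if b.attach_s is None:
                raise TreeValidationError(f"branch {b.id!r}: missing attach_s")
            if not (parent.s[0] <= b.attach_s <= parent.s[-1]):
                raise TreeValidationError(
                    f"branch {b.id!r}: attach_s outside parent arc-length range"
                )
        # connectivity / acyclicity: every branch must reach the root
        for b in self.branches.values():
            seen = set()
            cur = b
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise TreeValidationError(f"cycle through branch {cur.id!r}")
                seen.add(cur.id)
                cur = self.branches[cur.parent_id]
            if cur.id != self.root_id:
                raise TreeValidationError(f"branch {b.id!r}: disconnected from root")

    def path_to(self, loc: TreeLocation) -> list[tuple[Branch, tuple[float, float]]]:
        """Chain of (branch, s-interval) from the ostium origin to ``loc``.

        The returned intervals are contiguous: the path runs along each
        ancestor from its origin to the attachment point of the next
        branch, and along the final branch up to ``loc.s``.
        """
        b = self.branch(loc.branch_id)
        if not (b.s[0] <= loc.s <= b.s[-1] + 1e-12):
            raise TreeLookupError(
                f"location s={loc.s} outside branch {b.id!r} range"
            )
        segs = [(b, (float(b.s[0]), float(loc.s)))]
        while b.parent_id is not None:
            attach = b.attach_s
            b = self.branches[b.parent_id]
            segs.append((b, (float(b.s[0]), float(attach))))
        segs.reverse()
        return segs

    def path_length(self, loc: TreeLocation) -> float:
        return sum(s1 - s0 for _, (s0, s1) in self.path_to(loc))


def resample_branch(branch: Branch, step: float) -> Branch:
    """Resample the area profile onto a uniform arc-length grid.

    Uses shape-preserving monotone-cubic (PCHIP) interpolation so the
    resampled areas never overshoot the bracketing input samples — a
    plain cubic spline can undershoot at a stenosis shoulder and create a
    phantom lesion.  ``step`` is the maximum grid spacing (m); endpoints
    are preserved exactly.  If ``step`` exceeds the branch length the
    result keeps only the two endpoints.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_seg = max(1, math.ceil(branch.length / step - 1e-9))
    grid = np.linspace(branch.s[0], branch.s[-1], n_seg + 1)
    area = PchipInterpolator(branch.s, branch.area)(grid)
    area[0] = branch.area[0]
    area[-1] = branch.area[-1]
    xyz = None
    if branch.xyz is not None:
        xyz = np.column_stack(
            [np.interp(grid, branch.s, branch.xyz[:, k]) for k in range(3)]
        )
    return Branch(
        id=branch.id,
        parent_id=branch.parent_id,
        attach_s=branch.attach_s,
        s=grid,
        area=area,
        xyz=xyz,
        occluded=branch.occluded,
    )


def resample_tree(tree: CoronaryTree, step: float) -> CoronaryTree:
    """Resample every branch of ``tree`` (see :func:`resample_branch`)."""
    branches = {bid: resample_branch(b, step) for bid, b in tree.branches.items()}
    return CoronaryTree(branches=branches, root_id=tree.root_id, meta=dict(tree.meta))


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise TreeFormatError(f"missing key {key!r} in {where}")
    return obj[key]


def load_tree(path) -> CoronaryTree:
    """Read a CTREE-JSON geometry file and return a validated tree (SI)."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TreeFormatError(f"malformed JSON in {path}: {exc}") from exc
    fmt = _require(doc, "format", "document")
    if fmt != FORMAT_TAG:
        raise TreeFormatError(f"unsupported format tag {fmt!r}")
    root_id = _require(doc, "root_id", "document")
    branches: dict[str, Branch] = {}
    for braw in _require(doc, "branches", "document"):
        bid = _require(braw, "id", "branch record")
        pts = _require(braw, "points", f"branch {bid!r}")
        s, area, xyz = [], [], []
        has_xyz = pts and all(k in pts[0] for k in ("x_mm", "y_mm", "z_mm"))
        for p in pts:
            s.append(_require(p, "s_mm", f"point of branch {bid!r}") * MM)
            area.append(_require(p, "area_mm2", f"point of branch {bid!r}") * MM2)
            if has_xyz:
                xyz.append([p["x_mm"] * MM, p["y_mm"] * MM, p["z_mm"] * MM])
        attach = braw.get("attach_s_mm")
        branches[bid] = Branch(
            id=bid,
            parent_id=braw.get("parent_id"),
            attach_s=None if attach is None else attach * MM,
            s=np.array(s),
            area=np.array(area),
            xyz=np.array(xyz) if has_xyz else None,
            occluded=bool(braw.get("occluded", False)),
        )
    meta = dict(doc.get("meta", {}))
    meta.setdefault("source_units", {"length": "mm", "area": "mm2"})
    tree = CoronaryTree(branches=branches, root_id=root_id, meta=meta)
    tree.validate()
    return tree


def save_tree(tree: CoronaryTree, path) -> None:
    """Write a validated tree to a CTREE-JSON file (clinical units)."""
    tree.validate()
    doc = {
        "format": FORMAT_TAG,
        "root_id": tree.root_id,
        "branches": [],
        "meta": {k: v for k, v in tree.meta.items() if k != "source_units"},
    }
    for b in tree.branches.values():
        rec = {
            "id": b.id,
            "parent_id": b.parent_id,
            "attach_s_mm": None if b.attach_s is None else b.attach_s / MM,
            "points": [],
        }
        if b.occluded:
            rec["occluded"] = True
        for i in range(b.n_points):
            p = {"s_mm": b.s[i] / MM, "area_mm2": b.area[i] / MM2}
            if b.xyz is not None:
                p["x_mm"], p["y_mm"], p["z_mm"] = (b.xyz[i] / MM).tolist()
            rec["points"].append(p)
        doc["branches"].append(rec)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def tree_to_frame(tree: CoronaryTree):
    """Per-point table (branch_id, s_mm, area_mm2) for CSV export."""
    import pandas as pd

    rows = []
    for b in tree.branches.values():
        for i in range(b.n_points):
            rows.append((b.id, b.s[i] / MM, b.area[i] / MM2))
    return pd.DataFrame(rows, columns=["branch_id", "s_mm", "area_mm2"])
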