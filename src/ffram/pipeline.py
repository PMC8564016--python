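"""End-to-end orchestration: geometry → lesions → flows → FFR → report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, apply_config
from .flow import (FlowAssignment, allocate_branch_flows, hyperemic_flows,
                   total_resting_flow)
from .lesions import Lesion, find_lesions, grade_stenosis, lesion_table
from .pressure import FfrProfile, ffr_profile, mean_aortic_pressure
from .tree import CoronaryTree, resample_tree
from .units import MM

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one FFR computation produced."""

    tree: CoronaryTree
    lesions: list[Lesion]
    flows: FlowAssignment
    profile: FfrProfile
    pa: float
    q_total: float
    ffr_table: pd.DataFrame = field(repr=False, default=None)
    lesion_report: pd.DataFrame = field(repr=False, default=None)


def analyze_tree(tree: CoronaryTree, ctx, cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full analytical FFR pipeline on one tree + patient context."""
    cfg = cfg or RunConfig()
    ctx = apply_config(ctx, cfg)
    work = resample_tree(tree, cfg.grid_step_mm * MM)

    lesions: list[Lesion] = []
    for branch in work:
        lesions.extend(find_lesions(
            branch, window=cfg.smooth_window_mm * MM,
            ds_min=cfg.ds_min, throat_tol=cfg.throat_tol,
        ))
    log.info("detected %d lesion(s)", len(lesions))

    pa = mean_aortic_pressure(ctx.sbp, ctx.dbp, offset=cfg.pa_offset_mmhg)
    q_total = total_resting_flow(ctx)
    rest = allocate_branch_flows(work, q_total, exponent=cfg.scaling_exponent)
    by_branch: dict[str, list[Lesion]] = {}
    for les in lesions:
        by_branch.setdefault(les.branch_id, []).append(les)
    flows = hyperemic_flows(work, rest, by_branch, ctx.hyperemia)

    profile = ffr_profile(
        work, flows, lesions, pa, cfg.fluid(ctx),
        ischemia_threshold=cfg.ischemia_threshold,
        ffr_floor=cfg.ffr_floor,
        include_bernoulli_net=cfg.include_bernoulli_net,
    )

    ffr_tab = profile.to_frame(work, flows)
    les_tab = lesion_table(lesions)
    if not les_tab.empty:
        les_tab["grade"] = [grade_stenosis(l.ds) for l in lesions]
        les_tab["q_ml_s"] = [r.q_ml_s for r in profile.lesion_reports]
        les_tab["dp_ps_mmHg"] = [r.breakdown.dp_ps for r in profile.lesion_reports]
        les_tab["dp_ss_mmHg"] = [r.breakdown.dp_ss for r in profile.lesion_reports]
        les_tab["dp_sd_mmHg"] = [r.breakdown.dp_sd for r in profile.lesion_reports]
        les_tab["dp1_mmHg"] = [r.breakdown.dp1 for r in profile.lesion_reports]
        les_tab["dp2_mmHg"] = [r.dp2 for r in profile.lesion_reports]
        les_tab["ffr_distal"] = [r.ffr_distal for r in profile.lesion_reports]
        les_tab["ischemic"] = [r.ischemic for r in profile.lesion_reports]
    return PipelineResult(tree=work, lesions=lesions, flows=flows,
                          profile=profile, pa=pa, q_total=q_total,
                          ffr_table=ffr_tab, lesion_report=les_tab)


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, cfg: RunConfig, out_dir,
                  input_paths: dict[str, str] | None = None) -> dict:
    """Write ffr.csv, lesions.csv, flows.csv and provenance.json.

    Outputs are deterministic (pinned float formatting, sorted JSON
    keys, no timestamps): identical inputs and config give byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.9g"
    result.ffr_table.to_csv(out / "ffr.csv", index=False, float_format=fmt)
    (result.lesion_report if result.lesion_report is not None
     else pd.DataFrame()).to_csv(out / "lesions.csv", index=False,
                                 float_format=fmt)
    result.flows.to_frame().to_csv(out / "flows.csv", index=False,
                                   float_format=fmt)
    prov = {
        "tool": "ffram",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "inputs": {
            name: _file_digest(p) for name, p in (input_paths or {}).items()
        },
        "pa_mmHg": result.pa,
        "q_total_ml_s": result.q_total,
        "n_lesions": len(result.lesions),
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return prov
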