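import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ffram as F
from ffram.tree import Branch, CoronaryTree

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fluid():
    return F.FluidProperties()


@pytest.fixture
def patient():
    """Cohort-typical scalars: LVM 115 g, cuff 134/77 mmHg."""
    return F.PatientContext(lvm=115.0, sbp=134.0, dbp=77.0, hct=0.42)


def random_tree(rng, max_branches: int = 6) -> CoronaryTree:
    """Small random tree with gently varying areas; always valid."""
    n_br = int(rng.integers(1, max_branches + 1))
    branches = {}
    ids = []
    for i in range(n_br):
        bid = f"b{i}"
        length = float(rng.uniform(8e-3, 30e-3))
        n = int(rng.integers(8, 40))
        s = np.linspace(0.0, length, n)
        r0 = float(rng.uniform(0.8e-3, 2.0e-3))
        r = r0 * (1.0 + 0.1 * np.sin(2 * math.pi * s / length * rng.uniform(0.5, 2)))
        if i == 0:
            parent, attach = None, None
        else:
            parent = ids[int(rng.integers(0, i))]
            ps = branches[parent].s
            attach = float(ps[-1]) if rng.random() < 0.6 else float(
                rng.uniform(0.3, 1.0) * ps[-1]
            )
        branches[bid] = Branch(id=bid, parent_id=parent, attach_s=attach,
                               s=s, area=math.pi * r * r)
        ids.append(bid)
    tree = CoronaryTree(branches=branches, root_id="b0")
    tree.validate()
    return tree


def linear_taper_lesion(rng, branch_id: str = "x"):
    """Random linear-radius three-segment lesion plus its exact Branch.

    The closed-form taper drop is exact for linear radius, so the
    numeric oracle must agree with the analytic assembly on this
    geometry to quadrature accuracy.
    """
    from ffram.lesions import Lesion

    r_p = float(rng.uniform(1.0e-3, 2.0e-3))
    r_d = float(rng.uniform(0.8, 1.2)) * r_p
    ds = float(rng.uniform(0.3, 0.8))
    r_s = min((1 - ds) * max(r_p, r_d), 0.95 * min(r_p, r_d))
    L = float(rng.uniform(6e-3, 16e-3))
    lps = float(rng.uniform(1.5e-3, 0.45 * L))
    lsd = float(rng.uniform(1.5e-3, 0.45 * L))
    bp = [0.0, lps, L - lsd, L]
    grid = np.unique(np.concatenate([np.arange(0, L, 0.02e-3), bp, [L]]))
    r = np.interp(grid, bp, [r_p, r_s, r_s, r_d])
    branch = Branch(id=branch_id, parent_id=None, attach_s=None,
                    s=grid, area=math.pi * r * r)
    lesion = Lesion(
        branch_id=branch_id, s_prox=0.0, s_dist=L,
        s_throat_start=lps, s_throat_end=L - lsd,
        A_p=math.pi * r_p**2, A_s=math.pi * r_s**2, A_d=math.pi * r_d**2,
        alpha=math.degrees(math.atan((r_p - r_s) / lps)),
        beta=math.degrees(math.atan((r_d - r_s) / lsd)),
        ds=ds,
    )
    return branch, lesion
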