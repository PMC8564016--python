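# ffram — analytical fractional flow reserve from coronary lumen geometry

`ffram` estimates fractional flow reserve (FFR) — the ratio of the
pressure distal to a coronary stenosis to aortic pressure under maximal
hyperemia — directly from a reconstructed coronary-tree geometry and a
handful of scalar patient inputs, with no CFD simulation.  It is aimed
at researchers in computational hemodynamics who want a transparent,
fast, closed-form baseline for CT-derived FFR, together with the
diagnostic-evaluation statistics (ROC/AUC, DeLong, Bland–Altman, 2×2
metrics) used to benchmark such indexes against invasive FFR.

## The model

For a point distal to a lesion,

```
FFR = 1 − (ΔP₁ + ΔP₂) / Pa
```

* **Pa** — mean aortic pressure during hyperemia, estimated from cuff
  pressures as `DBP + (SBP − DBP)/3 − 6.8` mmHg.
* **ΔP₂** — Hagen–Poiseuille loss from the coronary ostium to the
  lesion's proximal end, integrated over the measured lumen-area
  profile `∫ 8πμ q(s)/A(s)² ds` with each branch's own hyperemic flow.
* **ΔP₁** — drop across the lesion, decomposed into three segments
  (contracting taper `L_ps`, maximally stenosed throat, expanding taper
  `L_sd`), each the mechanical analogue of a contracting, straight, or
  expanding pipe:
  * `ΔP_ps` = viscous taper drop + entrance loss
    `ζ_c (ρ/2) q² (1/A_s − 1/A_p)²`, `ζ_c = 0.5 (1 − A_s/A_p)^{3/4} sin α`;
  * `ΔP_ss` = Poiseuille drop over the throat at area `A_s`;
  * `ΔP_sd` = viscous taper drop + Borda–Carnot-type separation loss
    `ζ_e (ρ/2) q² (1/A_s − 1/A_d)²`, `ζ_e = min(1, 2.6 sin β)`.

The anatomical inputs `A_p, A_s, A_d, L, L_ps, L_sd` and the entrance /
exit angles `α, β` are measured automatically from the lumen-area
profile by the lesion-analysis module.  Flow is driven by physiology:
total resting coronary flow is linear in left-ventricular mass
(`q0 = 0.8` mL·min⁻¹·g⁻¹ by default), allocated over bifurcations by a
flow–diameter scaling law (exponent 7/3), and multiplied at hyperemia
by a stenosis-dependent factor `k(DS)` falling from 4.0 (DS ≤ 0.3) to
1.0 (DS ≥ 0.9).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Generate a synthetic LAD-like vessel with a 60% diameter stenosis and
compute its FFR profile:

```sh
$ ffram synth --preset single-lad --ds 0.6 --out fix
$ ffram compute --tree fix/tree.json --patient fix/patient.json --out out
Pa=89.2 mmHg  Q_total=1.533 mL/s  lesions=1  min distal FFR=0.597
```

`out/lesions.csv` holds the detected lesion's anatomy and hemodynamics:

```
 ds  L_mm  A_s_mm2  alpha_deg  beta_deg  q_ml_s  dp1_mmHg  dp2_mmHg  ffr_distal  ischemic
0.6    11    1.131     14.421    14.421   3.833    35.174     0.734       0.597      True
```

Reading: the patient's hyperemic aortic pressure is 89.2 mmHg (cuff
134/77) and total resting coronary flow 1.533 mL/s (LVM 115 g).  The
detector found one moderate lesion (DS 0.60, length 11 mm, throat
1.13 mm²); hyperemic lesion flow is 3.83 mL/s (k = 2.5 at DS 0.6), the
lesion itself costs 35.2 mmHg while the healthy upstream segment costs
only 0.7 mmHg, giving a distal FFR of 0.597 — well below the 0.80
ischemia threshold, so the vessel is flagged ischemic.

`out/ffr.csv` carries the per-point FFR profile, `out/flows.csv` the
branch flows, and `out/provenance.json` the configuration and input
hashes that make the run reproducible.  Other subcommands: `ffram synth
--preset cohort` (virtual cohorts with a manifest), `ffram lesions`
(anatomy only), `ffram eval` (diagnostic metrics + DeLong comparisons
from a paired CSV), `ffram config` (write the full default YAML).

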