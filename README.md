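# coapvc

Partial volume correction for image-derived arterial input functions (AIF)
in dynamic PET, based on conservation of activity (CoA), together with a
digital flow-phantom validation pipeline and an irreversible two-tissue
compartment model to quantify the downstream kinetic impact.

## Who this is for

Dynamic PET kinetic modelling needs the blood curve feeding the tissue —
the AIF — which often must be read from a small artery (internal iliac,
carotid; 5–10 mm) because the aorta lies outside the scanner's axial field
of view. At PET's 4–7 mm resolution such vessels lose most of their signal
to the partial volume effect (PVE): the mean activity in the true vessel
contour can be depressed by 50% or more. `coapvc` implements the CoA
corrections that recover the true curve from the spilled signal, the
synthetic phantom that validates them end-to-end without scanner data, and
the kinetic model that shows why the correction matters.

## The corrections

With `C`/`V` the mean activity / volume of the true vessel region (`A`),
an enlarged spill-out region (`SO`) containing all its blurred signal, a
background ring (`BKG`), and an optional companion vein (`V`):

* zero background: `C_corr = C_SO·V_SO / V_A`
* with background: `C_corr = (C_SO·V_SO − C_BKG·(V_SO − V_A)) / V_A`
* artery + vein sharing one spill-out region: the background-subtracted
  total is split between artery and vein in proportion to their
  image-derived signals `C_A·V_A` and `C_V·V_V`, then divided by each true
  volume.

A classical recovery-coefficient correction (`C_A / RC`, background-blind)
is included as the baseline it outperforms: below background, RC-corrected
curves stay artificially inflated, which can drive the fitted trapping
rate k₃ of an irreversible 2-tissue model to zero.

## Worked example

Run the full phantom validation (simulate → extract → correct → report)
with defaults — four artery tubes (25.4 → 6.35 mm) plus a companion vein,
one shared input function, 1.4 kBq/cc background, 6 mm FWHM blur,
15 × 20 s frames:

```python
from coapvc import RunConfig, run_validation_experiment

summary = run_validation_experiment(RunConfig(seed=1))
cols = ["tube", "method", "auc_kbq_s_cc", "auc_pct_error",
        "peak_kbq_cc", "auc_improvement_pts"]
print(summary.table[cols].to_string(index=False,
      float_format=lambda v: f"{v:.1f}"))
```

```
         tube      method  auc_kbq_s_cc  auc_pct_error  peak_kbq_cc  auc_improvement_pts
artery_25.4mm uncorrected        1912.6          -13.1         31.8                  0.0
artery_25.4mm  background        2197.9           -0.1         37.6                 13.0
artery_25.4mm          rc        2274.9            3.4         37.8                  9.7
artery_12.7mm uncorrected        1635.4          -25.7         26.1                  0.0
artery_12.7mm  background        2201.9            0.1         37.6                 25.6
artery_12.7mm          rc        2382.0            8.3         38.0                 17.4
 artery_9.5mm uncorrected        1455.3          -33.9         22.5                  0.0
 artery_9.5mm  background        2209.1            0.4         37.8                 33.4
 artery_9.5mm          rc        2472.8           12.4         38.1                 21.4
artery_6.35mm uncorrected        1156.1          -47.4         16.4                  0.0
artery_6.35mm  background        3906.0           77.5         55.1                -30.1
artery_6.35mm artery-vein        2285.5            3.9         36.1                 43.6
artery_6.35mm          rc        2745.3           24.8         38.9                 22.7
```

Reading the table: the ground-truth AUC of every artery tube is
2200 kBq·s/cc (delivered activity / flow = 22 MBq / 10 mL/s). Uncorrected
AUC errors worsen monotonically as the tube shrinks (−13% → −47%); the
background-subtracted CoA correction restores the three solo tubes to
within half a percent. For the paired 6.35 mm artery/vein tubes the naive
single-tube equation overcorrects by +78% (the vein's signal is inside
the shared spill-out region), while the artery/vein apportioning lands
within 4%. The recovery-coefficient baseline over-recovers AUC because it
keeps inflating the curve after the true activity falls below background.

The same objects are available piecewise — `generate_input_function`,
`render_dynamic_image`, `build_region_set`, `extract_tac`,
`coa_correct_background`, `TwoTissueIrreversibleModel(...).fit()` — and
from the command line:

```bash
coapvc simulate --out-dir sim/            # 4-D NIfTI + ground-truth TACs
coapvc extract  --image sim/phantom.nii.gz --center 50 50 30 \
                --radius 4.75 --length 20 --out tac.csv
coapvc correct  --method background --c-so so.csv --c-bkg ring.csv \
                --v-a 1.418 --v-so 55.4 --out aif.csv
coapvc fit      --tissue tumour.csv --input aif.csv --out params.json
coapvc validate --out-dir results/        # the full table above
```

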