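# bonescrew

Model-based torque-limit estimation for bone screws.

Over-tightening a bone screw strips the threads the screw has formed in the
bone (or bone-surrogate foam), destroying the fixation; under-tightening
risks loosening. `bonescrew` implements the estimation chain a smart
screwdriver needs to individualise the torque limit during the insertion
itself:

1. **Strength identification.** Insertion torque is modelled as cutting plus
   thread friction,

   τ(φ) = σ₍ucs₎·G₁ + μ_T·σ₍ucs₎·(φ − α/2)·G₂,

   where φ is the screw rotation, σ₍ucs₎ the host material's ultimate
   compressive strength (MPa), μ_T the thread friction coefficient, and
   G₁, G₂ (mm³) closed-form functions of the screw/hole geometry. Because
   the model is linear in its single unknown, σ₍ucs₎ is identified from a
   recorded insertion segment by through-origin linear least squares,
   σ̂ = Σ τᵢxᵢ / Σ xᵢ² with xᵢ = G₁ + μ_T·G₂·(φᵢ − α/2) — closed form, no
   iteration.

2. **Stripping-torque prediction.** The identified strength is converted to
   a predicted thread-stripping torque via shear failure of the material on
   the cylindrical screw envelope (area A_C = π·D_s·L, shear direction θτ),

   τ_fail = (σ₍ucs₎/√3)·A_C·[⅓·(D³_head − D³_shaft)/(D²_head − D²_shaft)·μ_H·sin θτ − (D_s/2)·cos θτ],

   optionally divided by a stress-concentration factor k_t ≥ 1 (brittle
   bound; the uncorrected value is the ductile bound).

3. **Signal processing.** Recorded torque/rotation/position traces are
   cropped to the moving portion, the tightening onset is detected from the
   smoothed torque derivative (first crossing of 6× its 90th percentile),
   and the empirical stripping torque is the maximum of the median-filtered
   torque.

4. **Synthetic rig.** A simulator emulates a motorised test rig (30 RPM,
   1 kHz sampling, 0.25° encoder, 0.025 mm draw-wire, 25 N·mm torque noise)
   inserting an ISO 5835 HB 6.5 cancellous screw into eight polyurethane
   foam grades until stripping, with full ground truth — so every stage and
   the end-to-end chain are testable without laboratory data.

5. **Statistics.** Pearson correlations with Fisher-z confidence intervals,
   a Fisher z-test for comparing correlations, linear calibration and
   Bland–Altman agreement summaries.

The package is written for biomechanics researchers and instrument
developers. The core identification step is a scikit-learn estimator
(`InsertionStrengthRegressor`) and composes with sklearn tooling.

## Worked example

```python
import bonescrew as bs

geom = bs.ScrewGeometry.hb65()            # HB 6.5 screw, 3.2 mm pilot hole
mat = bs.MaterialSpec("M330", 4.0)        # 4 MPa rigid PU foam
trace, truth = bs.simulate_insertion_trace(mat, geom, seed=7)

record = bs.process_trace(trace)          # segment + identify + predict
print(f"identified strength: {record['sigma_hat']:.3f} MPa "
      f"(generated {truth.sigma_ucs_true:.3f})")
print(f"predicted stripping torque: {record['tau_pred_no_kt']:.0f} N·mm")
print(f"measured stripping torque:  {record['tau_true']:.0f} N·mm")
```

prints

```
identified strength: 4.000 MPa (generated 4.000)
predicted stripping torque: 3060 N·mm
measured stripping torque:  3118 N·mm
```

The identified strength reproduces the generated one to 0.01 % despite full
sensor noise and quantization; the predicted stripping torque (ductile
bound, no stress-concentration correction — the reference screw's
γ = (D_shaft − D_minor)/p is negative, so k_t is undefined for it) agrees
with the torque measured from the same trace to about 2 % (the generator
jitters the realised stripping peak around the model value to emulate
lot-to-lot material variation).

The same chain is available from the shell:

```sh
bonescrew simulate --out-dir traces --n-per-material 10 --seed 1
bonescrew run traces/*.csv --summary summary.json --records records.csv
bonescrew predict --sigma-ucs 4.0
```

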