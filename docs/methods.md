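# Methods

This note documents the models, the numerical and design choices, and the
limits of what the synthetic validation can show.

## Insertion-torque model and strength identification

During self-tapping insertion the screw thread plastically deforms the hole
wall; the wall pushes back with a normal stress of roughly the material's
ultimate compressive strength σ_ucs (the material yielded to deform and does
not unload). Integrating the resulting friction traction (and the much
smaller cutting contribution of the tapered tip) over the engaged surface
gives a torque linear in σ_ucs:

    τ(φ) = σ_ucs·G1 + μ_T·σ_ucs·(φ − α/2)·G2

with geometry-only coefficients

    θ   = atan(p / (π·Ds))                      pitch (helix) angle
    rf  = (Dh + Ds)/4,  rs = (2Dh + 2Ds)/6      effective friction/cutting radii
    Ac  = tanβ·((Ds − Dh)/2)²                   cutting cross-section
    Kf0 = (Ds − Dh)/2·(1 + tan²β)·√(((Ds+Dh)/4)² + (p/2π)²)
    G1  = rs·Ac/cosθ,   G2 = 2·rf·Kf0/cosθ.

All internal units are mm, MPa, N·mm, rad and s, so MPa·mm³ = N·mm and no
hidden factors appear; config files and trace CSVs use degrees and N·m and
are converted once at the I/O boundary.

**Engagement offset α.** The friction term grows with the engaged thread
surface, which lags the rotation by the taper engagement: the model uses
(φ − α/2). The package derives α from the tip taper by default
(`from-taper-geometry`): the tip must cut radially from Dh to Ds, which at
taper half-angle θt takes an axial length L_taper = (Ds − Dh)/(2·tan θt),
i.e. α = 2π·L_taper/p revolutions of rotation (≈ 2.18 rad for the reference
geometry, reading the printed 60° as the half-angle). This derivation is a
package choice — the offset is not standardised — so an `explicit-value`
policy allows overriding α (also via `alpha_rad` in geometry configs), and
the policy used is recorded in output metadata. For φ < α/2 the friction
term would be negative; it is clamped to zero and such samples are excluded
from fitting (the cutting-only regime is poorly described by the clamped
form). The fit range actually used is reported in the estimate.

**Identification.** With x(φ) = G1 + μ_T·G2·(φ − α/2) the model is a
through-origin regression with one parameter; the least-squares minimiser is
the closed form σ̂ = Σ τᵢxᵢ / Σ xᵢ². There is deliberately no intercept (the
physical model has none) and no robust/weighted variant in this version. A
negative σ̂ (possible on pathological input) is returned with a flag rather
than raised, so batch QC can see it. By default the rotation used for
fitting is derived from the draw-wire position (φ = 2π·Δposition/p), because
the encoder rotation outpaces axial advance while the threads engage
("engagement slip"); fitting on raw encoder rotation is available behind a
flag.

## Stripping-torque model

At tightening, the axial load between the screw head and the internal
threads shears the engaged material over the cylindrical envelope of the
screw (area A_C = π·Ds·L). With the shear direction
θτ = atan2(p, π·Ds) + atan2(1, −μ_T) — obtuse for any μ_T ≥ 0, and
monotonically *increasing* in μ_T — the failure torque is

    τ_fail = (σ_ucs/√3)·A_C·[⅓·(Dhead³ − Dshaft³)/(Dhead² − Dshaft²)·μ_H·sin θτ
                             − (Ds/2)·cos θτ],

linear in σ_ucs (cos θτ < 0 makes the second bracket term a positive
contribution). A stress-concentration factor

    kt = 1 + [1 + 1.5·tanh(0.3·ln γ + 0.7)]·γ,   γ = (Dshaft − Dminor)/p

captures sharper thread tips locally raising stress; it is applied by
*dividing* τ_fail and represents the brittle-failure bound, while the
uncorrected τ_fail is the ductile bound. For the reference HB 6.5 screw the
shank (2.8 mm) is thinner than the thread core (3.0 mm), so γ < 0 and kt is
**undefined**; this is treated as a reportable state (NaN), not an error —
predictions default to the ductile bound (`kt_mode="none"`), and both bounds
are always carried on the prediction object. A speculative
ductility-interpolated prediction τ_fail/kt^d with d ∈ [0, 1] is provided as
an explicitly experimental function and excluded from default reports.

## Signal processing

- **Cropping.** Start = first sample strictly more than 1° of rotation from
  rest; end = first sample within 1° of the maximum rotation. Both
  thresholds are parameters.
- **Tightening onset.** Torque is smoothed with a centered moving average of
  1 s (window converted from seconds with the trace's actual sample rate, so
  other rigs are handled), differentiated with central differences
  (per-sample units; the threshold is relative, so per-second differencing
  is equivalent), and the onset is the first sample where the derivative
  exceeds 6× its 90th percentile. The percentile is taken over the whole
  cropped trace, and a blanking period of 2 screw revolutions after the
  crop start suppresses engagement spikes. The detector is invariant to
  torque rescaling by construction. Note an implicit design constraint: the
  elevated-derivative region (tightening plus one smoothing window) must
  occupy less than 10 % of the cropped trace, otherwise the 90th percentile
  itself is elevated and no crossing exists; recordings should therefore
  contain the full insertion, not a clip around tightening.
- **Stripping torque.** Maximum of the torque after a 0.03 s centered median
  filter, which suppresses single-sample spikes but preserves plateaus.
- **Filters.** Both filters force odd windows (even requests are widened by
  one sample) and shrink their windows at the edges; no padding constants
  are invented. The moving average is linear and both filters commute with
  additive constants.
- Segmentation indices must satisfy start < tightening ≤ stripping ≤ end or
  the composed segmentation raises.

## Synthetic rig simulator

The generator emulates the bench protocol: a screw driven at 30 RPM into a
pre-drilled foam block until the threads strip, recorded at 1 kHz.

Phases (with defaults): settle 1 s of zero torque; engagement over 1.5
revolutions during which the position advances at 0.3× pitch per revolution
(slip) and the torque ramps linearly up to the model value; insertion, where
the torque *is* the forward model evaluated at the position-derived
equivalent rotation at the drawn strength; tightening, a linear torque rise
from the insertion end to the stripping peak over 0.5 revolutions;
stripping, a 0.06 s peak hold followed by a quadratic decay over 0.75
revolutions to a 30 % residual plateau held for 0.5 revolutions. Sensor
effects are applied last: rotation rounded to 0.25° steps, position to
0.025 mm steps (both therefore within half a step of truth), Gaussian
torque noise with 25 N·mm SD (0.5 % of a ±5 N·m range). Everything is
reproducible from the seed.

Choices worth knowing:

- **Depth origin.** Axial advance starts at the sample where rotation first
  exceeds the bite angle (default 1°, equal to the default crop start
  threshold). This makes the pipeline's position-derived rotation agree
  exactly with the generator's model argument, so the zero-noise round trip
  recovers the generated strength to machine precision — a strong end-to-end
  consistency check, not a claim about real rigs.
- **Strength draw and peak jitter.** The per-insertion strength is the
  nominal value times a lognormal factor (CV 5 % by default), and the
  realised stripping peak gets an independent lognormal jitter of the same
  CV around the model prediction, emulating lot-to-lot material and
  hole-preparation variation.
- **Material-dependent depth.** Harder foams engage more slowly; effective
  insertion revolutions scale with nominal strength as
  clip(1.4 − 0.04·σ, 0.6, 1.4)·9. This spreads the ratio of final insertion
  torque to stripping torque across grades (≈ 0.2–0.45), as observed on
  real foams; with a fixed depth the ratio would be constant across
  materials because both torques are linear in strength.
- **Default cohort.** Eight grades at data-sheet strengths (0.8, 1.6, 4, 10,
  17, 3, 10, 12.5 MPa; midpoints of printed ranges), ten insertions each.
  Ductility weight is 0 for all (kt is undefined for the reference screw).
- **Sensor range.** Peaks above 5 N·m set a `clipped` metadata flag but the
  signal is not saturated: half the default grades exceed the range under
  this model, and clipping them would destroy the cohort-level round trip
  the simulator exists to support. Real recordings of such materials would
  saturate; treat flagged traces accordingly.

What the simulator does *not* model: any finite-element or contact-mechanics
realism, depth-varying strength (layered bone), friction variability,
manual axial-force assists, seating slips of the head against the plate, or
unscrewing after stripping. Passing tests on synthetic cohorts therefore
demonstrate internal consistency of the estimation chain and its robustness
to sensor noise/quantization at realistic levels — not accuracy on real
bone or foam.

## Statistics

Pearson r is computed with scipy; its confidence interval uses the Fisher z
transform, tanh(atanh r ± z_q/√(n−3)). Two correlations are compared with
the two-sided Fisher z-test
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). For the reference cohort
arithmetic (r = 0.977 and r = 0.926 at n = 80) these give 95 % intervals
[0.964, 0.985] and [0.887, 0.952] and p = 2.1·10⁻⁴; a quoted lower bound of
0.886 for the second interval reflects rounding of an unprinted r. The
two-sided convention is used because it reproduces p ≈ 0.0002 (one-sided
would give 0.0001).

Cohort summaries report an in-sample OLS calibration (observed ~ predicted,
as a deployed instrument would be bench-calibrated), then Bland–Altman bias
and 1.96·SD limits of agreement of the calibrated predictions, in absolute
form and in the conventional percentage-of-pair-mean relative form. The
mean absolute relative error uses the *measured* torque as denominator and
is reported separately, since the two relative conventions differ.

## Problem sizes and numerical notes

The validation suite uses full-length simulated recordings (23–35 s at
1 kHz, i.e. 2–3·10⁴ samples per trace): 8 noise-free round-trip traces, 100
noisy traces per material for recovery statistics, 100 traces for onset
accuracy, and an 8×10 cohort for end-to-end correlation — sizes chosen to
give stable Monte-Carlo statistics at interactive runtimes. The
closed-form identification is cross-checked against a 10⁵-point brute-force
SSE grid on 50 random segments (agreement within one grid step) and against
scikit-learn's intercept-free OLS. Geometry coefficients are locked against
a 40-digit independent evaluation at 10⁻¹² relative tolerance.

Degenerate inputs: empty segments, all-φ<α/2 segments and zero regressors
raise estimation errors; zero-variance inputs raise analysis errors; traces
must be uniform within 1 ppm. Ties in the onset detector resolve to the
first qualifying sample; the stripping index is never allowed to precede
the detected onset.

## Known limitations

- The insertion model assumes a homogeneous, isotropic, bilinear-elastic
  host and a uniform trapezoidal thread; layered or graded bone yields a
  weighted-average strength estimate and is out of scope here.
- Friction coefficients are configuration inputs (0.2 thread/foam, 0.45
  head/plate by default); identified strength scales nearly inversely with
  μ_T, so friction uncertainty propagates almost directly.
- The kt expression is undefined for screws whose shank is thinner than the
  thread core — including the reference screw — so stress-concentration
  corrections there require an externally supplied factor.
- No torque-limit policy layer (e.g. "stop at 80 % of predicted") is
  included; the package ends at the prediction and its statistics.
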