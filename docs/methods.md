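# Methods

## The 0D stenosis model

A straight segment (length l, radius r₀) with a focal throat (length L_s,
radius r_s = r₀(1−σ), σ the fractional **diameter** reduction) carrying
steady flow Q of an incompressible Newtonian fluid is reduced to three
additive pressure-loss terms:

1. baseline viscous loss over the full segment, 8μlQ/(πr₀⁴);
2. throat viscous loss over L_s at the reduced radius, 8μL_sQ/(πr_s⁴),
   present only for σ > 0;
3. form (separation) loss ½ρζ(Q/A_s)² with β = (1−σ)², ζ = (1/β − 1)².

**Composition mode.** The default, `additive-throat`, adds the throat term
on top of the *full-length* baseline, i.e. the throat window's own
reference-radius contribution is counted twice. This double count is what
the reference severity table was generated with, so it is the reporting
convention; it overstates the total by 8μL_sQ/(πr₀⁴) (≈0.07 mmHg at rest
for the defaults — negligible against any stenotic loss). The physically
consistent serial decomposition is available as `replace-throat`.

**Outputs.** P_d = P_a − ΔP; FFR = P_d/P_a clamped to [0, 1] for reporting
(raw value retained; clamped table cells render as `~0.00`); throat
velocity V = Q/A_s; Poiseuille wall shear τ_w = 4μQ/(πr_s³). The clamp
fires with a warning rather than an error because supra-proximal losses are
the model's honest statement that flow at the imposed rate is impossible —
the 0D model imposes Q, it does not solve for it.

**Assumptions.** Newtonian, laminar, quasi-1D flow; a single focal
axisymmetric lesion; compliance and inertance held constant across σ (focal
narrowing changes local resistance, not global wall elasticity or blood
inertia). No transition/turbulence modelling: beyond ~75% the printed losses
(10³–10⁶ mmHg) are formula extrapolations signalling "flow collapse", not
physiological pressures.

**Defaults.** l = 30 mm, r₀ = 1.5 mm, L_s = 5 mm, h = 0.2r₀, E = 0.4 MPa,
ρ = 1060 kg/m³, μ = 3.5×10⁻³ Pa·s; rest Q = 1.0 mL/s, hyperemia 3.0 mL/s,
P_a = 100 mmHg; severity grid σ ∈ {0, 0.25, 0.50, 0.75, 0.90}. All internal
computation is SI; mmHg (133.322 Pa) and mL/s convert at the interface.

**Severity bins.** The printed clinical mapping leaves gaps (≤25% mild,
30–60% moderate, 70–80% severe, ≥90% critical); we close them with
half-open bins mild < 0.30 ≤ moderate < 0.70 ≤ severe < 0.90 ≤ critical so
every σ ∈ [0,1) is classified and σ ≤ 0.25 is always mild.

**Compliance formula.** Source material prints the wall compliance both
with and without the length factor (and once as a garbled inverse); we use
C = 3πr³l/(2Eh), the only dimensionally consistent volume compliance
(m³/Pa) of the set.

## The analog circuit

The board is two symmetric series cells feeding one parallel peripheral
cell. No explicit netlist is printed for the hardware, so the canonical
netlist is an assumption, chosen to honour the described topology and every
named component:

    source → R1 → L1 → node A (C1 → gnd) → R2 → L2 → node B (C2 → gnd),
    parallel cell at B: R3 ∥ P1(variable, "stenosis") ∥ C3; output at B.

The variable resistor sits in the **parallel peripheral cell** (it is
described as a parallel/peripheral element, and only this placement
reproduces the measured behaviour: output voltage rising monotonically with
resistance, the electrical signature of pressure build-up against a
downstream obstruction). Printed values: R1 = 71.6 Ω, R2 = 0.8 Ω,
R3 = 83.4 Ω, C = 490 nF, L = 0.000209 mH. Unprinted values are filled by
assumption: C3 = 490 nF (same as C1/C2), L1 = L2 = the single printed L,
P1 full scale 1 kΩ (spanning a wide monotone output range over the
2.5%→100% sweep). These printed component values are consumed as given
constants — the unit system that would derive them from the arterial
parameters is not reconstructable — and the whole netlist is overridable
via JSON.

The solver is textbook complex MNA (node admittance matrix plus one current
unknown for the ideal source), solved directly; it is cross-checked in the
tests against an independent series/parallel impedance reduction of the
ladder. V_pp is defined as 2|U_out| and V_avg as the rectified cycle mean
(2/π)|U_out|, matching oscilloscope semantics; the waveform synthesiser
hard-clips at ±5 V (the excitation range) and recomputes both from the
final sampled cycle. The measured 40-level sweep recording ships as a
fixture for the statistics layer — it is a hardware artefact (component
tolerances, clipping, interference) that the ideal solver is *not* expected
to regenerate numerically.

## Calibration

ΔP = ΔU/k_P with k_P in V/mmHg (the source text writes the product form,
which is dimensionally inconsistent with its own unit statement; every
printed numeric use is the division). k_P defaults to the experimentally
calibrated 0.125 V/mmHg; the raw sensor data behind that number are not
published, so the constant ships as a constant. `fit_kp` performs
origin-constrained least squares (zero ΔU must map to zero ΔP) with a
seeded case-resampling percentile bootstrap (1000 draws) for the 95% CI;
whether the original calibration R² was origin-constrained is unstated, we
report the origin-constrained one against centered total variance, clipped
to [0, 1].

## Geometry

R(z) = R₀ − (ΔR/2)(1 + cos(2π(z−z_c)/L_s)) inside the throat window,
ΔR = R₀σ; C¹ at the window edges, minimum R₀(1−σ) at z_c. Defaults
L = 30 mm, R₀ = 1.5 mm, L_s = 5 mm, z_c = 15 mm, millimetre units in-file
(`scale=0.001` for SI). Meshing: 64 circumferential samples; the axial grid
is locally refined (spacing ≤ L_s/20 in the throat, ≤ 1 mm outside) —
resolution choices are ours, no reference values exist. Open tubes have
exactly 2·nθ·(nz−1) triangles and two rim boundary loops; optional fan caps
(nθ triangles each) close them watertight. STL I/O is delegated to trimesh.

## Pulsatile extension

The physical board runs at a fixed 50 Hz sinusoid, so pulsatile physiology
is a simulation-side extension: Q(t) = Q̄ + Q_a sin(2πft) at 1.2–1.5 Hz
(sinusoid chosen as the minimal positive pulse; Womersley profiles are out
of scope), driven through the steady model sample by sample (quasi-steady:
the lesion responds instantaneously to flow). Because ΔP(Q) is convex for
σ > 0, the cycle-mean loss exceeds the loss at mean flow (verified
numerically as a Jensen check). The three-element Windkessel is integrated
in its standard split form p = Zq + p_c, C dp_c/dt = q − p_c/R (the printed
differential equation is typographically corrupted; we re-derived the
standard form), trapezoidal update from p(0) = 0, venous pressure zero;
steady-state gain (Z+R) and the large-C limit p ≈ Zq are tested.
Final-cycle statistics are the reported summaries.

## Statistics

- Quadratic fit ΔV_pp = a₀ + a₁σ + a₂σ² by OLS; R², RMSE, and per-
  coefficient 95% CIs by seeded case-resampling percentile bootstrap
  (1000 draws, seed 0 default). Constant-y input has R² ≡ 0 by convention.
- Breakpoint fit: continuous hinge y = b₀ + b₁x + b₂(x−c)₊, c searched over
  observed interior x; ties break toward the smallest candidate
  (deterministic, data-driven). The slope-doubling severity is
  σ* = a₁/(2a₂), defined for positive coefficients within [0, 1].
- Discrete Fréchet distance by the standard DP recurrence; tested against
  exhaustive coupling enumeration for short curves and against the
  Hausdorff lower bound.
- OAT sensitivity: ±20% one-at-a-time perturbations of a curve-valued
  model; per-cell failures are flagged, not raised.
- Repeatability: per-level mean/SD/CV across ≥2 series plus a two-sided
  paired t-test between first and last series (identical series give the
  degenerate p = 1).

## Clinical layer

ABI = min(ankle_L, ankle_R)/brachial; PSVR grading <2.0 / 2.0–4.0 / >4.0
(boundary values assigned to the moderate bin, since the printed wording is
"below 2.0" and "greater than 4.0"); ΔP_clin = 4(V²_sten − V²_prox) mmHg
(the factor 4 folds ½ρv² and Pa→mmHg for blood density). The packaged
cohort table carries group means ± SD for 20 patients in five severity
groups; patient-level records are not published, so patient-level
correlations cannot be recomputed — concordance is computed on group means
(dP_eq = ΔU/k_P vs ΔP_clin and vs ABI). The censored "<2 mmHg" gradient of
the normal group is stored as 1.0 ± 0.5 with its censoring note.

## What the synthetic generators emulate — and what they do not

`synth_sweep` reproduces the flat-then-steep monotone signature of the
measured sweep (a continuous hinge plus seeded Gaussian noise);
`synth_calibration_pairs` produces noiseless or relative-noise pairs on a
2–45 mmHg grid. They emulate curve *shape* and noise level, not hardware
artefacts (drift, clipping distortion, interference, component tolerances).
Tests passing on synthetic data therefore demonstrate correct recovery
machinery, not hardware fidelity.

## Known limits on desk-scale reproduction

Recomputable from first principles: the full severity table's
self-consistent cells, the velocity/WSS values, and the calibration
conversions (all covered by tests and the acceptance script). Not
recomputable: the experimental k_P (raw sensor data unavailable), the
measured sweep table itself (hardware), the voltage–resistance R² = 0.972
(the variable pairing is ambiguous — the worked `validate` command
documents the choices without asserting that value), and patient-level
clinical correlations (only group summaries are published). Two hyperemic
cells of the severity reference (75%, 90%) are printed in pascals rather
than mmHg; they are flagged `unit_suspect` in the fixture, excluded from
cell-by-cell diffs, and the model's mmHg values stand.
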