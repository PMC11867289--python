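# Methods

## The measurement model

Dynamic susceptibility contrast (DSC) MRI tracks a gadolinium bolus with
fast T2\*-weighted imaging. For a voxel with baseline signal S0 (mean of
the pre-contrast frames), the contrast-agent concentration estimate is

    C_m(t) = -ln[S(t)/S0] / (TE * r2*).

The transverse relaxivity r2\* is not known in absolute terms, so
concentration is carried in arbitrary relaxivity-scaled units; by default
`r2star = 1`, i.e. concentration equals the measured ΔR2\* in 1/s. Every
timing parameter (MTT, CTH, delay) and the extraction index are invariant
to this scale. The default acquisition mirrors a 75 s gradient-echo EPI
bolus scan: 46 frames at 1.65 s, TE 54 ms, 11 baseline frames.

Tissue and arterial curves obey the tracer-kinetic convolution

    k_H * C_m(t) = CBF * [ R(t) ⊗ C_a(t - δ) ],

with R(t) the tissue residue function, C_a the arterial input function
(AIF), δ the bolus delay from the AIF site to the tissue inlet, and k_H a
haematocrit/density correction. k_H defaults to 1 and is configurable; it
rescales CBF and CBV only and cancels from MTT, CTH, δ and AOEF. The
discrete forward model uses rectangle-rule convolution with step dt
(consistent with the synthesis direction, so forward and inverse share one
discretisation); sub-grid delays are realised by linear interpolation of
the AIF, never by rounding to whole frames, because the delays of interest
(~0.1–1 s) are far below dt = 1.65 s.

## Bezier residue functions

R(t) is a cubic Bezier curve with control points P0 = (0, 1),
P1 = (p1x, p1y), P2 = (p2x, p2y), P3 = (t_end, 0) and the orderings
0 ≤ p1x ≤ p2x ≤ t_end, 1 ≥ p1y ≥ p2y ≥ 0 — five free coordinates. The
orderings guarantee R(0) = 1, R non-increasing, R(t_end) = 0, so the
transit-time density h(t) = -dR/dt is non-negative with unit mass. The
constraint scheme is this package's contract; a variant with a non-zero
terminal residue value is deliberately not offered.

Evaluation solves x(s) = t by safeguarded Newton iteration with a
bisection bracket (isolated zeros of x'(s) are handled by the bracket).
MTT and CTH are polynomial integrals in the curve parameter,

    MTT = ∫₀¹ y(s) x'(s) ds        (degree 5),
    CTH = ∫₀¹ (x(s) - MTT)² (-y'(s)) ds   (degree 8),

computed exactly by order-5 Gauss–Legendre quadrature (exact to degree 9).
CTH is returned as the central second moment (s²) by default; the
standard-deviation convention is available via `cth(as_std=True)`. Note the
transit-time literature more commonly quotes the standard-deviation form;
both are exposed because the variance form is what the defining integral
states.

For the optimizer, the ordering constraints are mapped to the unit box:
p1x = a·t_end, p2x = p1x + b·(t_end − p1x), p1y = 1 − c,
p2y = p1y·(1 − d), with a, b, c, d ∈ [0, 1].

## Deconvolution

Seven parameters (a, b, c, d, t_end, CBF, δ) are fitted by bounded
nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective; ftol = xtol = gtol = 1e-8, ≤ 500 evaluations per restart) on
the concentration-domain residuals. Bounds: a–d in [0, 1];
t_end ∈ [dt, 0.8 × scan duration]; δ ∈ [0, 5 s];
CBF ∈ [0, 10·k_H·max(C_m)/area(C_a)]. The objective is multimodal, so the
fit is multi-started: one moment-matching heuristic start (delay from the
peak lag, CBF from the central volume relation) plus scrambled-Sobol
points over the bounded box, seeded — 8 starts by default, deterministic
per seed. The restart with the smallest SSE wins; ties go to the smaller
δ. No regularisation term is used: the monotone Bezier family itself is
the regulariser. Inside the optimizer the curve is sampled parametrically
on a fixed 257-point s-grid and interpolated onto the lag grid (error
≪ noise); all reported quantities are recomputed from the exact curve.

Flat or zero tissue curves return CBF = 0 flagged non-converged; batch
fitting isolates per-voxel failures without aborting.

### What recovery tests show

Noiseless phantoms are recovered essentially exactly (MTT < 0.5 % error, δ
to < 0.05 s). With Gaussian signal noise at baseline SNR 35 on a single
voxel, MTT errors are dominated by a flat valley of the objective: the
unconstrained Fisher information matrix at the truth is numerically
singular (two near-null directions inside the Bezier shape parameters,
strong MTT–δ anticorrelation, r ≈ −0.9), so per-voxel estimates scatter
far more than the residual noise would suggest, and increasing restarts
does not change the result (the optimizer reliably finds SSE at or below
the truth's). Whole-brain averages over many voxels, as used in the
cohort summaries, are much better behaved than single-voxel fits — which
is how such maps are interpreted in practice.

## Capillary oxygen extraction

A capillary is a three-compartment system (haemoglobin-bound oxygen,
plasma oxygen, tissue oxygen). Along the normalised position x ∈ [0, 1]
of a capillary with transit time τ,

    dC/dx = -k τ α_H [ P(C) - pO2_tissue ],

where P(C) is the plasma tension in Hill equilibrium with the bound
fraction: P = P50 (S/(1-S))^(1/h), S = C_b/B. Defaults (per condition):

| parameter | normal breathing | hyperventilation | units |
|---|---|---|---|
| k (exchange rate) | 118 | 118 | 1/s |
| P50 | 26 | 24 | mmHg |
| h (Hill) | 2.8 | 2.6 | — |
| pO2 (tissue) | 32 | 28 | mmHg |
| α_H (Henry) | 3.1e-5 | 3.1e-5 | 1/mmHg |
| B (Hb capacity) | 0.1943 | 0.1943 | ml/ml |

Two bookkeeping modes are exposed: by default the state is total blood
oxygen content with the plasma fraction carried in equilibrium
(C = B·S + α_H·P(S)); `carry_plasma=False` treats C as bound oxygen only.
The default is the physically complete reading; the difference is a few
percent of C. The inlet is C(0) = B·s_a0 + α_H·p_a0 with defaults
s_a0 = 1.0, p_a0 = 250 mmHg, representing arterial blood at an inspired
oxygen fraction of 0.5. These inlet values are literature-style defaults,
not measurements: absolute AOEF levels depend on them and should not be
over-interpreted — only contrasts between conditions are meaningful.

Because the right-hand side depends on k and τ only through u = kτx, a
single dense integration of dC/du (RK45, rtol 1e-8, atol 1e-13; saturation
clamped away from 1 where the inverse-Hill term diverges) serves every
transit time: Q(τ) = 1 − C(kτ)/C(0). Q(0) = 0, Q is non-decreasing and
saturates at the algebraic equilibrium bound 1 − C_eq/C(0) with
C_eq = B·S_eq + α_H·pO2, S_eq = pO2^h/(pO2^h + P50^h).

The apparent oxygen extraction fraction weights Q by the transit-time
density of the fitted residue,

    AOEF = ∫ h(τ) Q(τ) dτ = ∫₀¹ Q(x(s)) (-y'(s)) ds,

evaluated by adaptive quadrature against the cached ODE solution and
reported ×100 as an arbitrary-unit index in maps and summaries.

## Volume pipeline

Per in-mask voxel: signal → concentration → deconvolution → MTT, CTH, δ,
CBF maps; CBV = k_H · area(C_m)/area(C_a) (trapezoid) needs no
deconvolution; AOEF maps when a blood-gas preset is given. Failed or
degenerate voxels are set to 0, and whole-brain summaries are means over
strictly non-zero in-mask voxels. Delay summaries first drop values more
than 3 scaled MADs (1.4826 × median absolute deviation) from the median —
delay maps show sporadic spuriously high voxels. Baseline ROI SNR is
mean/SD over the pre-contrast frames (temporal for a single series,
pooled over voxels × frames for a stack, so the SD estimates the
per-voxel noise level). Runs are deterministic per seed; summary CSVs are
byte-identical across repeats.

## Synthetic phantoms

The generator emulates the study acquisition (75 s, dt 1.65 s, TE 54 ms,
11 baseline frames) and builds data forward through the same physics: a
gamma-variate AIF A(t−t0)^α e^{−(t−t0)/β} (defaults t0 = 18 s, α = 3,
β = 1.5, peak ΔR2\* ≈ 49 1/s — the arterial signal dips to ~7 % of
baseline, as saturated real AIFs do), tissue curves from the forward
convolution (default class: curved Bezier residue, MTT 3.8 s, δ 0.5 s,
CBF scale 0.065, giving a tissue peak ΔR2\* ≈ 11 1/s, i.e. a signal dip
to ~54 % of baseline — typical for this kind of protocol), exact inverse
signal conversion with S0 = 100, and Gaussian noise with SD = S0/SNR.
Gaussian rather than Rician noise is used because at baseline SNR ≥ ~20
the difference on magnitude data is negligible. Residue families: exact
Bezier and linear curves, plus boxcar (plug flow) and gamma-distributed
transit times tabulated on a 10 ms grid — the latter two are deliberately
outside the cubic Bezier family, stressing model mismatch.

What the phantoms do *not* emulate: anatomy and partial volume, motion,
T1 leakage effects, AIF measurement error (the fitted AIF is the true
one), and spatial noise correlation. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated model,
not robustness to real-data confounds.

## Cohort statistics

The paired comparison (n = 8 subjects, two conditions) uses: Shapiro–Wilk
screening (scipy's AS R94 implementation); a paired t-test for MTT, AOEF
and venous SNR; an exact two-sided Wilcoxon signed-rank test for the
non-normally distributed delay differences (the null distribution over
all 2^n sign assignments is obtained by the generating-function dynamic
programme, which enumerates the assignments exactly; midranks for ties;
zero differences dropped with a warning); a Bonferroni family gate at
α/4 = 0.0125 with strict inequality; and within-condition Pearson
correlation/regression against end-tidal CO2 (pooled analysis behind a
flag). "Average increase" means the mean of per-subject H/N ratios; the
ratio of column means is reported alongside, and matters most for the
skewed delays, where the two conventions give +129 % and +63 %
respectively. p-values are reported to 4 significant digits.

The fixture tables are checksummed on load. Arterial-velocity changes are
derived from delay prolongation as v_H/v_N = δ_N/δ_H (fixed path length),
and the central-volume-theorem helper combines CBV and CBF change factors
into an implied MTT factor (MTT = CBV/CBF).

## Numerical and design notes

- Curve inversion tolerance ~1e-13·t_end; quadratures for MTT/CTH are
  exact for their polynomial degree, verified against adaptive quadrature.
- The ODE at rtol 1e-8 agrees with an rtol 1e-10 run to < 1e-6 relative
  in Q; an independent content-state/DOP853 integration at rtol 1e-12 was
  used to freeze reference values for Q(1.0 s) and Q(3.8 s).
- AOEF quadrature raises if the adaptive error estimate exceeds its
  tolerance rather than returning silently degraded values.
- Degenerate inputs fail loudly: empty masks, zero AIF area, constant
  Shapiro input, all-zero Wilcoxon differences, non-positive signals
  (with the offending frame named).
- Problem sizes in the shipped tests are chosen to exercise every code
  path at comfortable runtimes: 3×3 to 8×8 phantom grids, 100-repeat
  noise studies, dense-grid oracles of 2·10^4–2·10^5 points.

## Known limitations

- Absolute AOEF depends on the assumed arterial inlet; only
  between-condition contrasts are interpretable.
- CBF/CBV are relative (arbitrary concentration units, k_H, AIF partial
  volume); no absolute calibration is attempted.
- Single-voxel delay and MTT estimates at realistic SNR carry large
  variance from the flat objective valley (see above); interpret maps
  through regional or whole-brain averages.
- No leakage correction, motion handling or automatic AIF detection.
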