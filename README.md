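# dscbezier

Bezier-constrained deconvolution of dynamic susceptibility contrast (DSC)
MRI bolus-tracking data, with capillary oxygen-extraction modelling and
paired cohort statistics.

## What it does, and for whom

DSC-MRI tracks a gadolinium bolus through the brain with fast
T2\*-weighted imaging. Deconvolving the tissue concentration curve with
the arterial input function (AIF) yields the tissue impulse response
CBF·R(t), where the residue function R(t) is the fraction of tracer still
in the tissue a time t after arterial arrival. Conventional SVD
deconvolution returns oscillating, partly negative R(t); this package
instead fits R(t) as a constrained cubic Bezier curve — monotone, R(0)=1,
R(t_end)=0 — so the transit-time distribution h(t) = −dR/dt is a proper
probability density. From the fit it derives:

- **MTT** — mean transit time, ∫R(t)dt (= CBV/CBF by the central volume
  theorem);
- **CTH** — capillary transit-time heterogeneity, the central second
  moment of h;
- **δ** — the bolus arrival delay between AIF site and tissue inlet
  (inversely related to arterial velocity), fitted sub-grid;
- **AOEF** — an apparent oxygen extraction fraction index,
  ∫h(τ)Q(τ)dτ, where Q(τ) is the extraction along one capillary from a
  three-compartment oxygen transport ODE
  dC/dx = −kτ·α_H·[P(C) − pO2] with Hill-equilibrium plasma tension P(C);
- **CBV**, relative CBF, baseline ROI SNR, and whole-brain summaries with
  a ±3 scaled-MAD outlier gate for delays.

It is aimed at perfusion-MRI researchers who want residue-function shape
metrics (rather than only the area under R) and a fully reproducible,
synthetic-data-validated reference implementation. No raw MRI ships with
the package: a phantom generator produces 4D volumes with known ground
truth through the exact forward physics, and per-subject cohort tables of
a normal-breathing vs hyperventilation study are included as fixtures.

## Worked example

```python
import dscbezier as dz

# synthetic voxel: ground truth MTT 3.8 s, delay 0.5 s
acq = dz.AcquisitionConfig()                      # 46 frames @ 1.65 s, TE 54 ms
aif = dz.gamma_variate_aif(18.0, 3.0, 1.5, 11.0, acq.times)
entry = dz.TissueClassSpec(family="bezier", mtt=3.8, cbf=0.065, delta=0.5)
tissue = dz.make_tissue_curve(entry, aif, acq)

model = dz.BezierDeconvolution(tissue, aif, acq)
result = model.fit(seed=0)
print(result.summary())
```

prints

```
Bezier deconvolution results
============================
converged       : True
restarts used   : 8
SSE             : 1.63941e-20
CBF (a.u.)      : 0.065
delay delta (s) : 0.5000
MTT (s)         : 3.7997
CTH (s^2)       : 4.1143
t_end (s)       : 7.3054
control points  : P1=(2.568, 0.747) P2=(4.534, 0.363)
```

i.e. the generating parameters are recovered (MTT error 0.01 %, delay
exact to 4 decimals) and the fitted control points describe the monotone
residue curve. Adding the blood-gas preset gives the extraction index:

```python
params = dz.condition_presets("normal_breathing")   # k=118/s, P50=26, h=2.8, pO2=32
print(round(100 * result.aoef(params), 1))          # 34.9  (a.u., x100)
```

The paired cohort analysis of the packaged study tables:

```python
results = dz.PairedCohort().fit()
print(results.summary())
```

reports, among other lines, MTT 3.76 → 4.99 s (+33 % mean per-subject
ratio, paired-t p = 0.0049), AOEF 22.5 → 29.0 a.u. (+30 %), venous SNR
−28 % (p = 0.0055), delay +63 % in ratio of means (exact Wilcoxon
p = 0.0078) — all significant at the Bonferroni gate α/4 = 0.0125 — and
an AOEF–ETCO2 correlation of r = −0.846 (p = 0.0081) during normocapnia.

A command-line interface mirrors the library:
`dscbezier fit|summary|snr|sim|cohort --help`.

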