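# qsmtrend

Quantitative susceptibility mapping (QSM) of iron-rich deep gray nuclei,
with synthetic aging phantoms, three dipole-inversion algorithms, and
age-trend statistics.

Brain iron accumulates with age, preferentially in the basal ganglia,
and tissue magnetic susceptibility χ measured by QSM is an established
proxy for non-heme iron content. `qsmtrend` implements the complete
analysis chain used in high-field ex vivo studies of the deep gray
nuclei — caudate (Cd), putamen (Pt), globus pallidus (Gp), substantia
nigra (Sn) — as a reusable, tested Python package:

1. **Synthetic phantoms** — a brain-shaped mask with four bilateral
   ellipsoidal nuclei whose susceptibility follows linear age models
   χ(age) = slope·age + intercept (ppm vs years), out-of-mask background
   sources, optional diamagnetic-voxel contamination of Gp/Sn, forward
   dipole field, gradient-echo phase accrual at B₀ = 9.4 T, complex
   Gaussian noise, and phase wrapping.
2. **Phase processing** — Laplacian-based phase unwrapping
   (∇⁻²(cos θ ∇² sin θ − sin θ ∇² cos θ)) and V-SHARP background-field
   removal (variable-radius spherical-mean-value filtering with
   truncated deconvolution).
3. **Dipole inversion** — the field-to-susceptibility problem
   F⁻¹DFχ = Φ with D(k) = 1/3 − k_z²/|k|², solved by
   * **TKD**: thresholded k-space division with 1/D clamped to
     sgn(D)/δ for |D| ≤ δ (pipeline default δ = 0.25), with an optional
     correction for the systematic underestimation of compact sources;
   * **L2**: closed-form minimizer of ‖F⁻¹DFχ − Φ‖² + λ‖Gχ‖² with
     L-curve selection of λ swept log-spaced over [10⁻⁴, 1];
   * **MEDI**: morphology enabled dipole inversion,
     argmin ‖M∇χ‖₁ + λ‖W(Φ − F⁻¹DFχ)‖₂², by IRLS with conjugate-gradient
     inner solves (λ default 1000).
4. **ROI statistics** — per-nucleus mean ± STD over three contiguous
   axial slices, bilateral pooling, optional tracing-jitter replication.
5. **Statistics** — Kolmogorov–Smirnov/Lilliefors normality, paired
   t-tests between nuclei, Pearson correlation with age, and
   least-squares age-trend fits with adjusted R².

Volumes are read and written as 3-D NIfTI-1 (nibabel); tables as CSV
(pandas). See `docs/methods.md` for model details and numerical
choices.

## Worked example

Run a four-subject noiseless synthetic cohort end to end (phantom →
field → wrapped phase → unwrap → V-SHARP → TKD δ = 0.25 → ROI stats →
trend fits):

```python
from qsmtrend import PipelineConfig, run_pipeline

cfg = PipelineConfig(ages=(2.0, 10.0, 18.0, 26.0), algorithm="tkd",
                     delta=0.25, rng_seed=1)
res = run_pipeline(cfg)
print(res.table.head(4).to_string(index=False))
for name, fit in res.fits.items():
    print(f"{name}: slope={fit.slope:.5f} ppm/yr  adj_r2={fit.adj_r2:.3f}  rho={fit.rho:.3f}")
```

prints

```
subject_id  age_years nucleus  mean_chi_ppm  std_chi_ppm algorithm                              params
       S00        2.0      Cd      0.006296     0.000745       tkd {'delta': 0.25, 'corrected': False}
       S00        2.0      Pt      0.005404     0.000541       tkd {'delta': 0.25, 'corrected': False}
       S00        2.0      Gp      0.007686     0.000901       tkd {'delta': 0.25, 'corrected': False}
       S00        2.0      Sn      0.006690     0.000317       tkd {'delta': 0.25, 'corrected': False}

Cd: slope=0.00190 ppm/yr  adj_r2=1.000  rho=1.000
Gp: slope=0.00301 ppm/yr  adj_r2=1.000  rho=1.000
Pt: slope=0.00184 ppm/yr  adj_r2=1.000  rho=1.000
Sn: slope=0.00420 ppm/yr  adj_r2=1.000  rho=1.000
```

Two things are visible here.  The linear age trend survives the whole
measurement chain perfectly (adjusted R² = 1.000, ρ = 1.000, and Sn
steepest > Gp > Cd > Pt, the expected nucleus ranking).  The raw TKD
slopes are attenuated by roughly the impulse-response factor
c(0.25) ≈ 0.70 relative to the generating models — the well-known
systematic underestimation of thresholded division, which grows with
δ.  Passing `TKDConfig(delta=0.25, correct_underestimation=True)`
divides the map by c(δ) and recovers absolute ROI means to within
about 12% (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
qsmtrend analyze --seed 1 --outdir out/          # cohort → roi_stats.csv, age_trends.csv
qsmtrend simulate --seed 1 --outdir sim/         # write phantom NIfTI volumes
qsmtrend recon --phase sim/S00/phase.nii.gz --mask sim/S00/mask.nii.gz \
               --algorithm tkd --delta 0.25 --outdir rec/
qsmtrend compare --seed 1 --outdir cmp/          # TKD/L2/MEDI battery on one subject
```

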