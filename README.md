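# renodce — automated renal DCE-MRI segmentation and GFR quantification

Dynamic contrast-enhanced MRI (DCE-MRI) can measure the glomerular
filtration rate of a *single* kidney, something serum creatinine or
tracer-clearance tests cannot do.  The bottleneck is segmentation: the
pharmacokinetic analysis needs the renal cortex isolated from medulla
and pelvis, and manual delineation is slow and poorly repeatable.

`renodce` implements a two-stage automated pipeline for 4D renal
DCE-MRI, aimed at researchers in quantitative renal imaging:

1. **Coarse segmentation** — a U-Net classifies each pixel of 96×96
   single-kidney patches (taken from the frames of peak cortical
   enhancement) as kidney/background; predictions are refined by
   largest-connected-component filtering.
2. **Fine segmentation** — each in-mask voxel's signal time-course is
   compressed by PCA into 20 feature aggregates and assigned to cortex,
   medulla or pelvis by an RBF-kernel SVM (multinomial logistic
   regression and XGBoost are provided as alternatives, discrete-wavelet
   features and k-means clustering as literature baselines).
3. **Quantification** — the mean cortical signal is converted to
   gadolinium concentration through the spoiled-gradient-echo signal
   equation and fitted with the two-compartment filtration model (2CFM):

   ```
   C_tissue(t) = Ktrans ∫₀ᵗ Cp_kid(τ) dτ + vp · Cp_kid(t)
   Cp_kid = Cp_art ⊗ g,   g(t) = (1/Tg)·exp(−(t−Δ)/Tg) for t ≥ Δ, else 0
   ```

   by trust-region-reflective least squares under physiological bounds
   (Ktrans ∈ [0.05, 0.40] min⁻¹, vp ∈ [0.2, 0.9], Δ ∈ [1.0, 3.5] s,
   Tg ≥ 0.02 s).  Single-kidney GFR follows as
   **SK-GFR = Ktrans × cortical volume** (mL/min, optionally normalized
   to 1.73 m² body surface area).

Because clinical DCE-MRI series are rarely shareable, the package ships
a first-class **synthetic phantom generator**: ellipsoidal kidneys with
cortex/medulla/pelvis shells (≈58/31/11 voxel mix), compartment
dynamics driven by the same forward 2CFM (cortex: early sharp uptake;
medulla: delayed steady rise; pelvis: late sigmoid accumulation), a
population arterial input function, SPGR signal formation and
Gaussian/Rician noise.  Every stage of the pipeline is validated
against this ground truth.  Repeatability and agreement statistics
(coefficient of variation with the √2 single-measurement factor,
paired t-test, Bland–Altman limits of agreement) round out the toolkit.

The U-Net and its training loop (SGD with momentum on binary
cross-entropy, best-validation checkpointing) are implemented in pure
NumPy with explicit backpropagation — deterministic for a given seed,
dependency-light, and gradient-checked against finite differences in
the test suite.

## Worked example

Fitting the 2CFM to the mean cortical curve of a noiseless phantom
(`python examples/02_fit_pk_model.py`):

```
fitted vs true 2CFM parameters:
  Ktrans [1/min]: 0.2500  (true 0.25)
  vp     [-]    : 0.4000  (true 0.4)
  delay  [s]    : 1.5000  (true 1.5)
  Tg     [s]    : 4.0000  (true 4.0)
residual sum of squares: 1.975e-24
SK-GFR (both kidneys' cortex): 23.76 mL/min = Ktrans x 95.0 mL cortex
```

All four parameters are recovered exactly on noiseless input; the
reported SK-GFR is the transfer constant times the 95 mL of cortex in
this small-matrix phantom.  The other scripts in `examples/` walk
through phantom generation, voxel classification (held-out balanced
accuracy 1.000 on phantoms), a miniature U-Net training run (held-out
whole-kidney IoU 0.977 in ~2 minutes) and the repeatability
statistics.

The same stages are available from the shell:

```sh
renodce simulate --seed 1 --out phantom/
renodce pipeline --seed 1 --out run/       # end-to-end on phantoms
renodce fit-pk --series s.nii.gz --labels lab.nii.gz --aif aif.csv --out report.json
```

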