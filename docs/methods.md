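# Methods

This note records the models, numerical choices and design decisions
behind `renodce`, and what the synthetic validation does and does not
establish.

## Pharmacokinetic model

Renal tissue is modelled as two compartments with no tubular outflow
within the acquisition window (an uptake-phase model).  The tissue
concentration is

    C_tissue(t) = Ktrans · ∫₀ᵗ Cp_kid(τ) dτ + vp · Cp_kid(t),

where Cp_kid is the intrarenal plasma concentration, obtained by
convolving the arterial input function (AIF) with a vascular impulse
response function (VIRF): a delayed, normalized exponential
g(t) = (1/Tg)·e^{−(t−Δ)/Tg} for t ≥ Δ.  Parameters and units:

| parameter | meaning | unit | bounds | note |
|---|---|---|---|---|
| Ktrans | intravascular→extravascular transfer constant | 1/min | 0.05 – 0.40 | converted to 1/s internally |
| vp | plasma volume fraction | – | 0.2 – 0.9 | a fraction; nonsensical as a volume |
| Δ | AIF delay | s | 1.0 – 3.5 | |
| Tg | dispersion time constant | s | ≥ 0.02 | optimizer upper bound 60 s (configurable): beyond the ~170 s window larger Tg is unidentifiable |

SK-GFR = Ktrans(cortex) × cortical volume.  When a body surface area is
supplied the value is also reported normalized to 1.73 m².

### Numerics

* All convolution/integration happens on a uniform internal grid
  (default 0.1 s).  Because the VIRF is exponential, the convolution
  solves Tg·y′ + y = f(t−Δ); we advance it with an exponential
  integrator that is *exact for piecewise-linear input* (implemented as
  a first-order IIR filter with an initial-condition correction), so
  the only discretisation error is the linear interpolation of the AIF.
  Against closed forms (step/constant AIF) the error is ~10⁻⁶ relative.
* The cumulative integral uses the trapezoidal rule on the fine grid.
* Fitting: `scipy.optimize.least_squares` (trust-region reflective)
  under the box bounds, restarted from 5 fixed interior points — the
  bound-box center and the 4 midpoints between the center and extreme
  corners — keeping the best residual.  Per-parameter at-bound flags
  are set within 10⁻⁶ of the box width.  Noiseless synthetic curves are
  recovered to ≪1% across an interior grid of true values.
* Signal↔concentration uses the SPGR steady-state equation with
  R1(t) = 1/T10 + r1·C(t); the inversion is closed-form.  Signals
  outside the invertible range (saturation) are clipped and flagged.
  Defaults (configurable): r1 = 3.6 L·mmol⁻¹·s⁻¹; T10 = 0.966 s
  (cortex), 1.412 s (medulla), 1.441 s (blood) — typical 1.5 T values.
  The phantom and the fitter share whatever values are configured, so
  synthetic validation is self-consistent by construction; the defaults
  are not claimed to match any particular scanner.

## Synthetic phantom

The generator emulates a 3D SPGR dynamic acquisition: 192×192×30
matrix at 2.2×2.2×3.0 mm, 74 frames every 2.3 s, 8 pre-contrast
frames, TR 2.36 ms, flip angle 20°.  Two ellipsoidal kidneys are
partitioned concentrically; relative shell radii 0.479 and 0.748 give
the ≈58/31/11 cortex/medulla/pelvis voxel mix reported for annotated
kidneys.  An aortic cylinder carries the AIF so ROI-based AIF
extraction can be exercised.

* **AIF**: gamma-variate bolus (amplitude 5 mmol/L, shape α = 2.5,
  time-to-peak 9 s) plus a recirculation/washout term, arriving at the
  first post-baseline frame.  Linear in amplitude, zero before arrival.
* **Cortex** (Ktrans 0.25/min, vp 0.40, Δ 1.5 s, Tg 4 s): early sharp
  vascular peak, then decline.
* **Medulla** (Ktrans 0.30/min, vp 0.20, Δ 3.0 s, Tg 30 s): the large
  dispersion and small vascular fraction make the filtration integral
  dominate, giving a monotone delayed rise that overtakes the cortex at
  late times — the physiological pattern.
* **Pelvis** is *not* a filtration compartment (it accumulates excreted
  contrast), so it uses a delayed sigmoid surrogate (half-rise 100 s,
  time constant 20 s, plateau 3 mmol/L), exactly zero before bolus
  arrival and dominating all compartments at late frames.
* **Noise**: Gaussian (default σ = 3% of mean baseline signal, clipped
  at zero as magnitude images are) or Rician.  The magnitude is a
  package choice; nothing in the emulated protocol pins it.
* **Heterogeneity**: `pk_dispersion` draws per-voxel parameter sets
  (quantized into 24 levels per compartment, truncated to the
  physiological bounds).  The default is 0, so noiseless voxels
  reproduce the forward model to machine precision; classification
  benchmarks use 0.15, a realistic biological coefficient of variation.

What the phantom does *not* emulate: breathing motion and registration
error, partial-volume mixing at compartment boundaries, B0/B1
inhomogeneity, anatomically realistic kidney shapes, inter-subject AIF
variability.  Consequently the synthetic benchmarks certify the
*machinery* (losses, gradients, fitting, data flow, statistics), not
clinical-grade accuracy: real-data scores will be lower, and the
k-means baseline — which fails on real data where cortex and medulla
overlap — can tie the supervised classifiers on phantoms whose classes
are separable by construction.

## Coarse segmentation

* **Architecture**: U-Net, depth 4; encoder blocks conv3×3–BN–ReLU,
  dropout 0.2, conv3×3–BN–ReLU, 2×2 max-pool; filters double from 64
  (default) to 1024 at the bottleneck; decoder blocks upsample by 2×2
  transposed convolution, concatenate the matching encoder map and
  apply two conv–BN–ReLU pairs (no dropout); 1×1 convolution + sigmoid
  head.  He-initialised.  Implemented in NumPy (im2col/matmul) with
  explicit backpropagation, verified against central finite
  differences; training is bit-reproducible for a fixed seed.
* **Training**: SGD, learning rate 0.01, momentum 0.99, binary
  cross-entropy (probabilities clipped at 10⁻⁷); the stored model is
  the epoch with minimum validation loss.  The validation split is by
  subject whenever provenance allows.  Batch size is free; the
  scaled-down benchmarks use 8, which at fixed epoch count doubles the
  number of SGD updates relative to the default 16 and converges
  within the 10-epoch budget.
* **Patches**: the 192-wide in-plane matrix splits into left/right
  96-pixel halves (other matrix sizes are center-cropped/padded to
  192).  Training patches take up to 10 vertical offsets per slice
  that keep ≥20% of the slice's kidney pixels (the minimum fraction is
  a package choice), each mirrored horizontally with probability 1/2;
  inference uses one centrally-located patch per side per slice.  Each
  patch is min-max normalized to [0, 1].
* **Frame selection** at inference is label-free: the frame maximizing
  the 95th percentile of baseline-subtracted signal within the central
  third of image rows (a band bracketing the kidneys), plus its two
  neighbours.  With the default geometry the cortex occupies more than
  5% of the band, so the 95th percentile tracks the cortical curve and
  the window centers on the cortical peak.  A series whose peak
  enhancement is below 2% of baseline raises a no-enhancement error.
* **Refinement**: largest connected component per side, 26-connectivity
  in 3D (a 2D option exists); ties are broken toward the component
  containing the lowest flat-index voxel and logged; an empty mask
  passes through with a warning.
* Binarisation threshold 0.5.

## Fine segmentation

* Time-courses are divided by their per-voxel mean baseline signal
  before PCA — coil gain does not transfer across subjects, and
  without this normalization cross-subject classification is
  ill-posed.  This choice is the package's own.
* PCA keeps k = 20 components, raised automatically until ≥90% of the
  training-cohort variance is explained.  Inputs on a different time
  grid are linearly resampled onto the training grid.
* Classifiers: RBF-SVM (γ = 0.05, C = 1; one-vs-one voting, no
  probability calibration), multinomial logistic regression (L2,
  stochastic-average-gradient solver), XGBoost (10 trees, depth 4,
  γ = 0.1, λ = 0.9, softmax objective).  Cortex and medulla training
  sets are resampled to the pelvis count (undersampling without
  replacement; oversampling if smaller).  A 5-fold grid search utility
  tunes (γ, C) by balanced accuracy with ties broken toward the
  simpler model (smaller C, then smaller γ).
* Baselines: Daubechies-4 DWT features (signals zero-padded to a
  multiple of 2^level so the periodized transform stays orthogonal and
  energy-preserving) classified with the same SVM; and k-means (k = 3)
  on the PCA features, with clusters mapped to classes by majority
  ground-truth vote *at evaluation time only* — deployable unsupervised
  labeling would need heuristics this package deliberately does not
  invent.
* Leave-one-subject-out discipline: PCA models and classifiers record
  their training subjects, and `classify_voxels` refuses mismatched
  cohorts.

## Statistics

* IoU (Jaccard) with the convention that two empty masks score 1.0
  (flagged); Dice/F1 = 2·IoU/(1+IoU).  Multiclass scores weight
  per-class IoU by ground-truth support; classes absent from the truth
  are excluded and flagged.
* Balanced accuracy = mean of per-class recalls; precision of a class
  never predicted is reported as 0 with a flag.
* Repeatability: σ_diff is the (n−1) sample SD of paired differences;
  the single-measurement SD is σ_sm = √2·σ_diff (a difference of two
  equally noisy measurements has √2 times their SD), and
  CoV = σ_sm/μ_pool·100%.  Reporting CoV without the √2 factor
  understates variability by 29%; the conversion between the two
  conventions is exercised in the tests.
* Bland–Altman: limits of agreement μ_d ± 1.96·SD with t-based
  confidence intervals (SE of a limit = SD·√(1/n + z²/(2(n−1)))), plus
  a Shapiro–Wilk normality p-value for the differences.

## Problem sizes used in the automated benchmarks

The shipped benchmarks are scaled to desk hardware as a package choice:
phantoms of 192×192×6–8 voxels; U-Net with base filters 16 trained for
10 epochs on ~250 patches from two synthetic subjects and evaluated on
a third (held-out whole-kidney IoU ≈ 0.98); classification on ~7k
held-out voxels; 81 noiseless parameter-recovery fits plus 50 noisy
Monte-Carlo replicates; end-to-end SK-GFR recovery within a few percent
of phantom truth.  All seeds are explicit and every benchmark is
deterministic given its seed.

## Known limitations

* Motion correction is out of scope; phantoms are motion-free, and real
  series are assumed registered upstream.
* Automatic AIF detection is not implemented: the AIF is an input
  (curve file or aorta ROI).  Hematocrit correction is off by default.
* The NumPy U-Net favours determinism and portability over speed; it is
  two or three orders of magnitude slower than GPU frameworks and meant
  for the published patch geometry, not large-scale training.
* The pelvis surrogate is phenomenological; fitted pelvis parameters
  have no physiological interpretation and the 2CFM is only ever fitted
  to cortex.
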