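# Methods

This note records the scientific and numerical choices behind the package:
the forward interference model, the reconstruction pipeline, the feature
and statistics definitions, what the synthetic tissue generator does and
does not emulate, and the known limitations.

## Forward interference model

The simulator represents a sample as discrete point backscatterers in a
homogeneous medium of refractive index *n* and bulk attenuation μ (mm⁻¹).
For each wavelength λ of the sweep the complex field at a camera pixel is

    E(x, y; k) = √I_ref · e^{i·2k·z_ref} + Σ_i √I_i(x, y) · e^{i·2k·z_i},
    k = 2πn/λ,

and the camera records `counts_scale · |E|²`.  Squaring the summed field
reproduces every term of the classical swept-source interference equation —
the reference intensity, the sample self-terms, the reference–sample
fringes `2√(I_ref·I_i)·cos(2k·Δz)` and the sample–sample (autocorrelation)
cross terms — without enumerating pairs.  The per-scatterer intensity

    I_i(x, y) = R_i · e^{−2μz_i} · exp(−((x−x_i)² + (y−y_i)²) / 2σ²)

combines the reflector strength `R_i`, round-trip single-scattering
Beer–Lambert decay, and a Gaussian transverse point-spread of σ = 4 μm
(matching a ~9 μm transverse resolution).  The PSF is truncated at 4σ and
the per-scatterer amplitude maps are held in a sparse matrix, so the cost
of a sweep is O(nnz × n_wavelengths) and dense speckle scenes stay cheap.

Design points:

- **Phase convention.**  The round-trip phase is `2·k·Δz` with `k` computed
  per frame from the true wavelength of a uniform-in-λ sweep (instruments
  step wavelength, not wavenumber).
- **Beads as single reflectors.**  Calibration beads (55 μm glass,
  index 1.95, in gel of index 1.33) are reduced to one top-surface point
  reflector with Fresnel reflectance `((1.95−1.33)/(1.95+1.33))² ≈ 3.6%`;
  internal bead optics are out of scope — beads only need to be resolvable
  targets at known depths.
- **Noise order.**  Poisson shot noise on the counts → additive Gaussian
  read noise → clip and quantize to the camera bit depth.  Seeds are split
  per noise source from one `NoiseConfig.seed`, so identical configurations
  are bit-reproducible.
- **Motion option.**  In vivo-like degradation is modelled as a rigid
  per-frame jitter: a common axial displacement enters the fringe phase,
  the transverse displacement rolls the sample field by whole pixels.  It
  models pulsation/respiration between frames, not intra-frame blur.
- **Aliasing guard.**  Scenes deeper than the unambiguous depth
  `λ_c²/(4·n·δλ)` are refused rather than silently folded.

### Scales

The instrument-scale sweep (1260–1345 nm at 0.042 nm, i.e. 2024 frames,
320×256 pixels) is available via `SweepConfig.full_scale()`.  The package
default is a scaled-down grid — the same 85 nm span sampled with 256
wavelengths on 64×64 pixels over a 450 μm field — chosen so that a full
simulate–reconstruct–featurize cycle takes well under a second and whole
studies (a few hundred volumes) run in minutes on one CPU.  The depth bin
of the scaled grid is ~3.6 μm (with the default zero-pad factor of 2) and
its unambiguous depth ~0.9 mm, comfortably beyond the 400 μm scenes.

Reference strength and scatterer reflectivities sit in the regime real
common-path systems are engineered for: `I_ref = 0.2` dominates the mean
per-scatterer sample intensity (~10⁻³) by two to three orders of magnitude,
keeping autocorrelation artifacts well below the reference–sample fringes.
At the default `counts_scale` of 2×10⁴ the fringe signal sits far above the
shot-noise floor while the reference level stays within a 16-bit range.

## Reconstruction

Per pixel: mean (DC) subtraction over the sweep; cubic-spline resampling of
the uniform-in-λ samples onto a uniform grid in `k = 2πn/λ` with the same
endpoints; Hann window; FFT with integer zero-padding; positive-frequency
magnitudes.  Depth calibration comes directly from the uniform wavenumber
spacing: bin *j* sits at `z_j = π·j/(N_fft·δk)`, equivalent to
`j·λ_c²/(2nΔλ·pad)` to first order.

- **Why resample.**  A uniform-λ sweep is chirped in k; transforming it
  directly smears deep peaks (measured: a 26% amplitude loss at 400 μm on
  the scaled grid, versus <1% after resampling).
- **Why Hann.**  Sidelobes of a rectangular window leak bright shallow
  structure across depth and would contaminate the co-occurrence texture.
- **Why pad 2.**  With no padding the peak of a reflector falls between
  bins (scalloping) by a depth-dependent amount, which biased attenuation
  slopes; a factor-2 pad flattens the recovered amplitude envelope across
  the usable depth range to <1%.
- **Magnitude, not log.**  Volumes store linear magnitude; log scaling is a
  display/feature-time concern, and the attenuation fitter needs linear
  units.  The positive-frequency half-spectrum is kept; the conjugate
  mirror is not unwrapped, matching a common-path geometry where all
  structure lies below the reference.

## Attenuation estimation

The estimator averages the backscattered **power** (squared magnitude) over
the transverse plane per depth bin and fits an ordinary least-squares line
to its natural log against depth; since the reconstructed magnitude of a
reflector decays as `e^{−μz}` (the fringe amplitude carries √I_samp), the
power profile decays as `e^{−2μz}` and μ = −slope/2.

Two numerical points matter:

- **Power domain.**  Detection noise adds *incoherently* to the signal
  field, so its expected contribution to mean power is an additive
  constant, whereas its contribution to mean magnitude is Rician and
  signal-dependent.  Fitting log mean power therefore allows an exact
  noise-floor correction; fitting log mean magnitude does not.
- **Floor subtraction.**  When a volume extends beyond the structure of
  interest, the mean power of bins deeper than `floor_from_um` (default
  500 μm in the feature pipeline) estimates the detector background and is
  subtracted before the fit.  Without it the flat floor drags the slope of
  strongly attenuating samples toward zero (at μ = 8 mm⁻¹ the deep end of
  the fit window is ~25× weaker than the shallow end).
- **Fit window.**  Default 40–380 μm: the first 10% of the 400 μm usable
  depth is skipped (surface artifacts), and the window stops half an axial
  mainlobe short of the end of the sampled tissue column, where the axial
  PSF loses neighbours and the binned mean droops.  On noise-free exact
  exponentials the estimator is unbiased to <2% across μ = 1–8 mm⁻¹; on
  simulated noisy volumes the 10-seed mean recovers μ within ~6%.

## Texture features

The flow is MIP along y (restricted to the first 450 μm of depth) →
max-pool onto 25 (depth) × 5 (transverse) tiles → min–max quantization to 8
gray levels → symmetric, normalized GLCMs at distance 1 for 0°, 45°, 90°
and 135° → per-matrix properties averaged over the four directions:

    contrast    = Σ P(i,j)·(i−j)²
    energy      = Σ P(i,j)²
    homogeneity = Σ P(i,j)/(1+|i−j|)
    correlation = Σ (i−μ_i)(j−μ_j)P(i,j)/(σ_i σ_j)

Choices: 8 gray levels keep a 125-pixel pooled image from spreading its
mass over too many matrix cells; the 25-cell axis runs along depth because
the y-MIP leaves a (depth × transverse) image whose long axis is depth; a
constant image gets correlation 0 by convention (σ = 0); the matrix op is
backed by `skimage.feature.graycomatrix`, while the properties are computed
here because the homogeneity kernel above is `1/(1+|i−j|)` rather than
skimage's `1/(1+(i−j)²)` (contrast and correlation are cross-checked
against skimage in the tests).

## Statistics

- **Mann–Whitney U**, two-sided everywhere (conservative default).  The
  exact enumerated null is used when the pooled sample has ≤ 12
  observations and no ties; otherwise the normal approximation with tie
  and continuity corrections (both via `scipy.stats.mannwhitneyu`).
- **Separability** `J = S_B/S_W` with `S_W = Σ_i Σ_{x∈D_i}(x−μ_i)(x−μ_i)ᵀ`
  and `S_B = Σ_i N_i(μ_i−μ)(μ_i−μ)ᵀ`.  Scalar features divide directly —
  this is the form used for per-feature comparisons; for vector features
  the trace ratio is reported, a deliberate extension since a ratio of
  matrices is otherwise undefined.  Zero within-class scatter with nonzero
  between-class scatter is flagged as infinite separability; the fully
  degenerate case raises.
- **SSIM** with the canonical parameters (Gaussian 11×11 window, σ = 1.5,
  K₁ = 0.01, K₂ = 0.03) on the joint dynamic range of the image pair.

## Classification protocol

Each reconstructed C-scan is split into two half C-scans along y, doubling
the sample count; the halves are tagged as siblings.  Features are (GLCM
contrast, GLCM correlation, μ).  The classifier is a Pipeline of
per-feature standardization and a linear soft-margin SVM (C = 1,
one-vs-rest for the three classes).  Evaluation:

- **Animal-held-out test split** — training and test samples never share an
  animal, so test accuracy measures generalization across subjects.
- **Stratified grouped 10-fold CV** inside the training set, with the
  standardizer refit per fold (no leakage) and sibling halves always in
  the same fold.  Grouping siblings is stricter than plain stratification
  and can only lower CV scores; the alternative risks optimistic bias from
  near-duplicate halves on both sides of a fold.
- **PCA** (top-2 components of the standardized features) is for
  visualization only; the SVM is fit in the 3-feature space, not on PCA
  scores.

## What the synthetic generator emulates — and what it does not

Three scene classes mirror the qualitative ex vivo signatures of rat brain
regions:

| class | emulates | signature |
|---|---|---|
| `homogeneous` | cortex / hippocampus | uniform speckle, μ ~ U(1, 4) mm⁻¹ |
| `white_matter` | corpus callosum | uniform speckle, μ ~ U(4, 8) mm⁻¹ |
| `striped` | striatum / thalamus | dark axial bands (100 μm wide, 100 μm gaps, 80% reflectivity suppression), μ ~ U(1, 4) mm⁻¹ |

The μ ranges follow reported ex vivo white/gray contrast (≈4–8 vs 1–4
mm⁻¹).  Scatterer density (3.5 per 10⁵ μm³, ≈2800 per scene) gives tens of
scatterers per depth bin — enough for a stable decay profile while keeping
desk-scale runtimes; per-scatterer reflectivities are exponentially
distributed around 10⁻³ to produce speckle-like amplitude variation.
Stripe width was chosen on the order of one pooled-grid column (~90 μm) so
the texture survives the 25×5 pooling, consistent with the coarse
downsampling being designed to capture sparse macro-features.

Passing tests on these scenes demonstrate that the pipeline recovers the
engineered contrasts (attenuation separates white from gray matter; GLCM
contrast/correlation separate striped from homogeneous gray matter) under
shot/read noise and across disjoint "animals".  They do **not** demonstrate
performance on real tissue: the generator has no vasculature, no
depth-of-field falloff, no dispersion, no tissue deformation, uniform
attenuation within a scene, and its "animals" differ only by random seed —
real inter-animal variability (myelin density, fiber orientation) is far
richer.  Accuracies on this synthetic cohort are therefore upper bounds
with respect to scene realism, not predictions for in vivo use.

## Degenerate inputs and edge conventions

- Quantization maps a constant image to level 0; a value exactly on a bin
  boundary rounds up.
- Empty scenes simulate to a constant reference level; reference-only
  stacks reconstruct to (numerically) empty volumes.
- `split_cscan` uses a floor/ceil split (161 → 80 + 81).
- An empty hold-out set is permitted (CV-only use); a class missing from
  the training set is an error.
- Depth cropping keeps absolute depths in the axis rather than re-zeroing,
  so attenuation windows remain physically meaningful.

## Known limitations

- The simulator's sample–sample autocorrelation terms are physical but the
  chosen reference-dominant regime keeps them small; studies of
  autocorrelation artifacts themselves should raise scatterer
  reflectivities deliberately.
- The attenuation model is single-scattering Beer–Lambert with a global μ
  per scene; no confocal/DOF correction is applied, and μ is fit over one
  global window rather than per A-scan.
- Motion jitter is rigid and per-frame; it does not model intra-frame blur
  or nonrigid tissue motion.
- The Mann–Whitney comparisons are reported without multiple-testing
  correction (few planned comparisons); raw p-values are given.
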