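# Methods

`mrtdose` studies whether a compact 3D convolutional dose engine, trained
exclusively on *high-noise* Monte-Carlo-style peak/valley dose maps, recovers
the underlying noiseless dose distribution of a microbeam radiation therapy
(MRT) field — the premise being that high-noise simulation data are far
cheaper to produce than converged dose maps, so a model that denoises while
it learns removes the main cost of building dose engines for novel,
preclinical treatment modalities.  This note records the models, the
synthetic data the package generates, and the numerical and design choices
behind them.

## Geometry and scoring model

MRT irradiates with coplanar, micrometre-wide synchrotron beamlets.  Dose is
described by two channels per 0.5 mm isotropic *macrovoxel*: the **peak**
dose scored in a 10 µm window on each beamlet track, and the **valley** dose
scored in a 100 µm window centred mid-pitch (pitch 400 µm, field 8 × 8 mm²).
A window's energy is assigned to the macrovoxel containing the window
*centre*; a centre falling exactly on a macrovoxel boundary ties toward the
lower index, and windows extending beyond the scored lattice are dropped.
The 400 µm pitch is incommensurate with the 500 µm voxel pitch, so some
voxels contain one window and some two; the centre rule resolves every case
deterministically.  The prediction volume is 48 × 8 × 8 mm³ = 96 × 16 × 16
macrovoxels, beam along axis 0.

The per-macrovoxel peak-to-valley dose ratio PVDR = peak/valley is the
biologically relevant summary; it is of order tens and decreases with depth
as scatter builds up.

## Phantoms

Phantoms are three-material label lattices (air, water-equivalent soft
tissue, compact bone) with densities 0.0012 / 1.000 / 1.85 g·cm⁻³.  CT
volumes can be segmented by HU thresholds (defaults −300/+300 HU, a typical
soft-tissue/bone split; the thresholds are configuration, not a claim about
any particular scanner).  A 5 mm water bolus is prepended on the beam-entry
face and the volume re-cropped to 96 depth layers so the model input shape
is constant.

The synthetic head generator emulates a rat-head-in-the-field geometry: an
ellipsoidal compact-bone skull shell (semi-axes 14–18 mm depth, 9–13 mm
lateral, shell 0.5–1.5 mm) whose crown faces the beam, brain (water)
inside, air outside, an ellipsoidal tumor (semi-axes 1.5–3 mm) placed fully
inside the brain, and optionally a small air cavity (auditory-canal
analogue) and a deep bone column (spine analogue), each present with
probability 0.5.  All draws are uniform within these ranges and
deterministic per seed.  What it deliberately does *not* emulate: organ
boundaries and soft-tissue contrast beyond three materials, partial-volume
HU effects, scanner noise, or anatomical left/right asymmetries.  Passing
tests on these phantoms therefore demonstrates the learning and evaluation
machinery under realistic geometry variation and noise, not anatomical
transfer to real rats.

## Augmentation

Each training sample is a base phantom transformed by a uniform draw of
lateral translation (±5 mm per axis), rotation about the brain centroid
(±10° per axis, intrinsic X→Y→Z order), and isotropic voxel-size scale
(0.8–1.2; scale s shrinks the anatomy's voxel count by ≈ s⁻³), resampled
with nearest-neighbour interpolation onto the fixed frame with air fill.
Nearest-neighbour keeps the three-material vocabulary exact and transports
the tumor mask with the identical mapping, so tumor voxels remain water by
construction.  Draws whose transformed tumor bounding box would leave the
lateral field are rejected and redrawn (the admissibility test maps the
eight bounding-box corners analytically, so manifests scale to thousands of
samples without resampling).  Per-sample seeds are spawned from the master
seed with `numpy.random.SeedSequence` and recorded in the JSON manifest.

Two discretization facts worth knowing: at this grid size the brain radius
is only ~6–12 voxels, so (i) a +10°/−10° rotation round trip recovers about
80 % of in-brain labels (double nearest-neighbour resampling of a label
field with a large surface-to-volume ratio), and (ii) volume scaling shows
aliasing of up to ~20 % at near-unity scale factors, while the same
operation on a 64 × 64-lateral lattice matches 1/s³ to < 1 %.  The property
tests assert the invariants at the resolution where discretization permits
and document the looser canonical-frame bounds.

## Surrogate dose model

A deterministic analytic stand-in replaces photon transport.  Per lateral
column, with exclusive radiological depth t(i) = Σ_{i'<i} µ(m_{i'})·Δz and
voxel-centre depth d_i:

    peak(i)   = mult(m_i) · exp(−t(i)) · (1 − exp(−d_i / d_b))
    valley(i) = s_max (1 − exp(−d_i / d_s)) · G_σ[peak](i)

where G_σ is a lateral Gaussian blur (σ = 1.5 voxels, nearest-edge
padding).  Defaults: µ = 10⁻⁴ / 0.02 / 0.06 mm⁻¹ and deposition multipliers
0.001 / 1.0 / 3.5 for air/water/bone, build-up d_b = 1 mm, scatter fraction
s_max = 0.05 with depth constant d_s = 10 mm.  These values give the
qualitative behaviour expected of a ~100 keV synchrotron microbeam field —
exponential falloff (the log-peak slope in water is exactly −µ_water beyond
build-up), bone enhancement at equal radiological depth by exactly the
multiplier ratio, strictly positive channels in-field, and PVDR of order
tens decreasing monotonically with depth in homogeneous water.  It is
stand-in physics: the absolute dose scale is arbitrary (a single scalar
calibrates to Gy at reporting time) and no claim of agreement with a
transport code is made.

## Replicate noise model

Monte-Carlo scoring noise is emulated per voxel by scaled-Poisson
replicates: replicate r scores K_r ~ Poisson(λ · D/D_ref) events and
estimates the dose as D_ref·K_r/λ, so the estimate is unbiased and the
relative standard error of the n-replicate mean is 1/√(n·λ·D/D_ref) —
low-dose voxels are noisier, as in real scoring.  D_ref is the median of
the channel's truth over in-field voxels (> 5 % of the channel maximum),
anchoring λ to the *typical* voxel and hence the mode of the SE histogram.

Regimes (n = 20 replicates throughout):

| regime | λ_valley | λ_peak | modal rel. SE (valley/peak) |
|--------|----------|--------|------------------------------|
| high   | 2.22     | 20     | ≈ 15 % / ≈ 5 %               |
| low    | 555      | 5000   | ≈ 0.95 % / ≈ 0.32 %          |

The high-noise budget follows from the targeted modes: 1/√(20λ) = 15 %
gives λ = 2.22, and 5 % gives λ = 20.  The low-noise regime is the
high-noise budget × 250, calibrated once so that ≈ 98 % of in-field valley
voxels fall below 2 % relative SE and ≈ 99 % of peak voxels below 0.5 % —
the regime's defining property.  High-noise data are used for training and
validation, low-noise (or noiseless truth) for testing, so test comparisons
are not dominated by reference noise.

## Dose engine

Two fully independent models (peak and valley), each mapping the
96 × 16 × 16 density matrix to one dose channel.  Inputs and targets are
affinely mapped to [0, 1] using the minimum and maximum of the *training*
partition only; validation/test data may leave [0, 1] and are never
clipped.  The architecture is a compact 3D U-Net, implemented in numpy with
hand-written backward passes (im2col + GEMM convolutions, JIT-compiled
gathers; gradients are verified against finite differences in the suite):

* compression: one stride-2 3×3×3 convolution per level (the study uses 4
  levels so the bottleneck's depth receptive field spans the whole 96-voxel
  attenuation column; lateral size 16 caps the depth at 4);
* bottleneck: one 3×3×3 convolution;
* decompression per level: nearest-neighbour 2× upsampling, concatenation
  with the mirror compression level's *input* (so the full-resolution skip
  is the density matrix itself), then two 3×3×3 convolutions;
* output: a linear 1×1×1 convolution, ReLU everywhere else, constant
  filter count per layer (the "filters" hyperparameter), He initialization.

Training minimizes the mean absolute error MAE = Σᵢ|yᵢ−xᵢ|/n on the
normalized scale with Adam; one seed governs initialization and batch
shuffling, and runs are bit-reproducible on a fixed BLAS backend.  Three
optimization choices matter for short single-core runs and are defaults
(each configurable): a cosine learning-rate decay to 5 % of the initial
rate, a faster Adam second-moment decay (β₂ = 0.99) when runs are only a
few thousand steps, and Polyak (exponential moving-average) weight
averaging with a ramped decay — the sign gradient of the MAE loss makes
the iterate wander around the optimum with a slowly varying global bias,
and averaging damps exactly that mode.  Small batches (down to 1) are
preferred at this data scale: an epoch costs the same arithmetic either
way, so smaller batches buy proportionally more optimizer steps.  Early
stopping: training halts when the validation MAE has not improved for
`patience` epochs and the best-validation-epoch (averaged) weights are
restored.  Validation-epoch selection uses the normalized-scale MAE (it is
the loss).
A NaN loss aborts with a divergence diagnostic, and diverged configurations
are recorded as non-convergent in the hyperparameter search table and never
selected.  Negative denormalized predictions are floored at zero (energy
deposition is non-negative); the floored fraction is reported.

Desk-scale study settings: 16 filters, batch 1, initial learning rate
2.5 × 10⁻³, 4 levels, 18 epochs.  The search schema expresses the
full-scale winning settings (64 or 128 filters, batch 8, learning rates
1–5 × 10⁻³) but the default grid is small.

## Evaluation statistics

* **MAE** per sample over a target region.
* **1σ consistency**: fraction of voxels with |pred − mean| ≤ k·SE.  With
  an unbiased prediction of noisy data ≈ 68 % is expected at k = 1;
  materially less indicates a systematic deviation, materially more
  indicates overfitting to the reference noise.  Voxels with zero SE are
  excluded from the denominator and counted.
* **ΔD_rel** = (D_ML − D_MC)/D_ML per voxel, reported as strict coverage
  fractions |ΔD_rel| < 3 % (satisfaction criterion; no spatial tolerance —
  voxel against voxel) and < 10 %, over the full volume, tissue-only
  (water voxels, excluding bone and air) and tumor masks.  Voxels with
  D_ML ≤ 0 are flagged undefined and excluded with a recorded count.
  Discretized maps use ±1/3/5/10 % magnitude steps.
* **PVDR** maps and ΔPVDR = (PVDR_ML − PVDR_MC)/PVDR_ML, with zero-valley
  voxels flagged.
* **Prescription consistency**: treatment time is set by scaling the plan
  so the minimum valley dose over the tumor reaches a prescription dose D*;
  comparing ML- and MC-planned irradiations gives
  ΔD = (min_MC/min_ML − 1)·100 %, independent of D* (it cancels), positive
  when the ML plan would deliver more dose than the reference requires.
  The ratio form obeys the exact antisymmetry
  ΔD(a,b) = −ΔD(b,a)/(1 + ΔD(b,a)/100).

## Problem sizes and reproducibility

The synthetic study in the test suite and analysis scripts uses 16 base
subjects (10 train / 3 validation / 3 test) augmented to 120 / 30 / 3
samples, 16-filter models, and up to a few tens of training epochs — sizes
chosen so the full study runs on a single desktop core in minutes while
leaving the noise regimes at their defining calibrations.  The
hyperparameter search stage and the full-scale manifest (4569/1431/500
samples) are exercised as bookkeeping at full scale but trained only at
desk scale.  Every stochastic step (phantom draws, augmentation,
replicates, initialization, shuffling) derives its seed from a single
master seed via `SeedSequence`; dataset files are written with HDF5
timestamps disabled, so re-running a pre-training stage with the same
configuration reproduces bitwise-identical files.

## What desk-scale training does and does not achieve

At the study sizes above, the engines robustly *denoise*: predictions are
far smoother than the training data and their error against noiseless
truth is well below the noise floor of the targets (MAE ratios of ~0.3–0.9
on held-out subjects), and validation 1σ-consistency fractions sit near
(slightly below) the unbiased 68 % expectation.  Absolute accuracy,
however, is limited by optimizer steps on one core and by generalization
across unseen geometries drawn from only a handful of base subjects:
in-tumor |ΔD_rel| < 3 % coverage typically lands between ~0.5 and ~0.9
per test subject and plateaus around ~0.85 (peak) even at three times the
default training budget, and the prescription-dose deviation — a minimum
statistic, maximally sensitive to local bias — can reach several percent.
Full-scale training (thousands of samples, 64–128 filters, orders of
magnitude more optimizer steps) is what pushes tumor coverage toward
100 %; the desk-scale study demonstrates the machinery and the denoising
effect, not that accuracy level.

## Known limitations

* The surrogate dose model has no lateral beam divergence, no energy
  spectrum, no buildup-region electron transport, and treats the valley
  purely as blurred, depth-weighted scatter of the peak channel.
* Three materials only; no organ-at-risk structures.
* Nearest-neighbour label resampling quantizes strongly at the 16 × 16
  lateral frame (see Augmentation above).
* The engine is trained for one beam configuration; changing the field
  size, pitch or windows requires retraining.
* Backend nondeterminism: results are reproducible for a fixed numpy/BLAS
  build; across BLAS implementations, reductions may differ in the last
  bits and training trajectories can diverge visibly even with identical
  seeds.
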