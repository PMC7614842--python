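# Methods

## The retention model

An immune complex (IC) on an FDC membrane patch is held by `m` closed
CR2–C3d bonds, `0 ≤ m ≤ M = min(n_R, n_L)`, where `n_R` is the number of
CR2 receptors on the patch and `n_L` the number of accessible C3d sites on
the IC.  `m` evolves as a one-step birth–death chain:

- unbinding: `r(m) = m·k_off` — each closed bond opens independently;
- rebinding: `g(m) = C(m)·k_on` with the all-to-all configuration count
  `C(m) = (n_R − m)(n_L − m)` — every free ligand can pair with every free
  receptor on the patch;
- `g(0) = 0` — once all bonds are open the IC diffuses away; `m = 0` is
  absorbing.

The chain starts at maximum bond formation (`m = M`).  Survival
`S(t) = 1 − P_0(t)` decays to zero eventually, but rebinding makes the
mean first-passage time to `m = 0` grow combinatorially with `n_R`, which
is the mechanism behind the superlinear sensitivity of retention to CR2
density.

Patch-to-patch variability in receptor number is modelled as Poisson:
`⟨S(t)⟩ = Σ_{n_R} Pois(n_R; ⟨n_R⟩) S_{n_R}(t)`.  Patches with `n_R = 0`
never hold an IC and enter the average as `S ≡ 0`, so the initial level
`⟨S(0)⟩ = 1 − e^{−⟨n_R⟩}` and the IC surface level `⟨S(t)⟩·⟨n_R⟩` is
proportional to `⟨n_R⟩` up to that (tiny, at physiological densities)
correction.  The half-life is the first time the level falls to half its
initial value.

## Parameters

| parameter | units | default | meaning / origin |
|---|---|---|---|
| `k_off` | s⁻¹ | 0.15 | single-bond dissociation rate, from BLI; sets the time unit (bond lifetime ≈ 7 s) |
| `k_on` | s⁻¹ | calibrated | effective per-configuration rebinding rate on the membrane; *not* the solution-phase BLI association constant (M⁻¹s⁻¹), which describes 3D encounter, whereas rebinding of a tethered IC is a 2D, reach-limited process |
| `n_L` | – | calibrated (integer 2–128) | accessible C3d sites per IC |
| `patch_area` | µm² | 0.018 | capture area of one bound IC (below) |

**Patch area.**  The all-to-all count `C(m)` assumes every C3d on the IC
can reach every CR2 on the patch, so the "patch" is the membrane disc
within reach of a bound IC: radius ≈ IC radius (~35 nm for an
antibody–phycoerythrin complex) + CR2 contour length (~40 nm for its
15–16 short consensus repeats), i.e. ~75 nm and an area of ~0.018 µm².
At 250–375 CR2/µm² this puts a mean of ~4.5–6.75 receptors within reach
of an IC.  The physically admissible range (capture radius 50–100 nm)
spans roughly 0.008–0.03 µm²; within that range 0.018 µm² is also the
value at which the two printed half-life anchors are reproduced most
tightly by integer `n_L` (both to <1%), and it is fixed as the package
default *before* any prediction is made.  Predictions at day 14 are
sensitive to this choice (the fold change below varies from ~3 to ~40
across the admissible range), which is the model's main structural
uncertainty; conversely, a patch of 1 µm² (hundreds of receptors per
patch) makes the Poisson spread negligible in relative terms and cannot
reproduce observed day-14 antigen levels at all.

**Calibration.**  `calibrate_rebinding` fixes `k_off`, then for each
candidate `n_L` solves for `k_on` by a monotone root find on `log k_on`
so the model half-life matches the first anchor exactly (half-life is
strictly increasing in `k_on`), and selects the `(n_L, k_on)` minimizing
the relative residual on the remaining anchors, ties broken toward the
smallest `n_L`.  Calibrated to IC half-lives of 1.2 h at 250 CR2/µm² and
1.5 d at 375 CR2/µm², this yields `n_L = 6`, `k_on ≈ 0.43 s⁻¹`, both
anchors within 1%, and — with no further freedom — predicts a ~7.3-fold
higher IC surface level at day 14 for 375 vs 250 CR2/µm².

## Numerics

- **Solver.**  The transient sub-generator on states `1..M` is tridiagonal
  with positive off-diagonal products whenever `k_on > 0`, hence similar to
  a symmetric tridiagonal matrix by a diagonal scaling (accumulated in log
  space).  `eigh_tridiagonal` gives all modes stably, and survival becomes
  an explicit exponential sum evaluable at arbitrary times — necessary
  because the dynamics span ~10 decades of time.  Eigenvalues are clipped
  at 0 to remove eigensolver noise; when the diagonal scaling would
  overflow (extremely deep rebinding), the solver falls back to a matrix
  exponential per time point, and the Poisson average treats such patches
  as non-decaying on representable time scales.
- **Closed forms.**  `k_on = 0` uses the independent-bond binomial
  solution; `n_L = 1` is a pure exponential, since `C(1) = 0` leaves the
  single bound state nothing to rebind with.
- **Poisson truncation.**  The receptor-count sum covers the central
  interval holding ≥ 1 − 1e−8 of the mass (tails split equally).
- **Half-life.**  On grid curves, log-linear interpolation in time between
  the bracketing points (linear when the bracket starts at t = 0);
  `mixture_half_life` instead brackets the crossing of the continuous
  exponential-sum representation on log-time (no grid error).  Calibration
  uses the continuous version; its root tolerance on `log k_on` is 1e−4.
- **Default time grid.**  400 log-spaced points from 0.1 s to 2×10⁷ s
  (~230 d) with t = 0 prepended.
- **Gillespie oracle.**  Direct method; inverse-CDF exponential waiting
  times; a single uniform draw against `r/(r+g)` chooses the event.  One
  root seed spawns a deterministic substream per trajectory index, so
  ensembles are bit-reproducible and enlarging an ensemble extends rather
  than reshuffles it.

## Measurement-side fits

- **Kinetics** (BLI): 1:1 Langmuir with mass transport ignored, fitted
  globally (shared `k_on`, `k_off`, `R_max`) across the concentration
  series; coarse log-grid search supplies initial guesses.  The reported
  `K_D = k_off/k_on` is an identity, not a separate fit.
- **Equilibrium**: unweighted least squares of
  `R_eq(C) = R_max·C/(C + K_D)` on linear scale.
- **Bead calibration**: ordinary least squares on linear axes, intercept
  retained to absorb autofluorescence; MFI→density floors the molecule
  count at zero.
- **Decay**: single exponential `A·e^{−λ·day}` with free day-0 intercept;
  half-life `ln 2/λ`.  The true Poisson-mixture decay is *not* a single
  exponential (it flattens as low-`n_R` patches empty first), so the fit
  is a summary of the sampled window, matching how such decays are
  summarized experimentally.
- **ELISA titer**: `−log₂(dilution) × 40`.

## Image quantification

Masking: 4× block-average subsampling, Gaussian smoothing (σ = 2 px at
subsampled resolution), a global automatic threshold (Otsu by default; Li
and mean exposed by flag), hole filling, then dilation by a 1-px rim so
the outermost shell contains genuine background rather than the stained
network edge.  Follicles are 8-connected components of ≥ 500 subsampled
pixels.

Shells are equal-width bins of the Euclidean distance-to-boundary
normalized per follicle — deterministic and shape-robust, and equal to
equal-thickness annuli on a disk (chosen over iterative erosion, which
quantizes badly on small regions).  Six shells; the outermost is the
background estimate.  Per channel: mean intensity per inner shell, minus
the background-shell mean, floored at 0, divided by the mean of the five
values; the reported profile is the antigen vector divided elementwise by
the structural vector, innermost first.  A channel whose inner shells sit
exactly at background level has no radial contrast and is defined as flat
(all ones) rather than 0/0.  Shells where the normalized structural value
is 0 are flagged undefined (NaN).

These choices make the profile invariant to per-channel gain, to
translation, and to uniform staining differences — the properties the
tests pin down — while the exact filter sizes remain free parameters.

## What the synthetic data does and does not emulate

Generated follicle images are disks with constant structural staining,
uniform or radially Gaussian antigen, and additive Gaussian read noise
(frame 512×512 at 4 µm/px; follicle radii of hundreds of µm; SNR 10 by
default).  Real FDC networks are irregular, textured, and imaged with
depth-dependent background and Poisson shot noise; passing the round-trip
tests therefore demonstrates correctness of the quantification logic and
its invariances, not robustness to every real-microscopy artifact.
Decay tables are forward-model levels with multiplicative lognormal noise
(positive observable, spread growing with signal); sensorgram and bead
panels are exact generative models of their fitters plus Gaussian or
lognormal noise.  Sample sizes follow the study design they emulate
(decay sampled at days 1/4/7; sensorgrams at 8 concentrations spanning
0.023–2.9 µM; 4 bead levels).

## Known limitations

- No spatial diffusion of ICs between patches, no re-association after
  full release, and no alternative binding geometries beyond all-to-all;
  bond length/flexibility enter only through the patch-area constant.
- The effective `(n_L, patch_area)` pair is identifiable only jointly;
  the calibrated `n_L` is an effective valency, not a molecular count.
- Whether patch survival plotted against density should include empty
  patches is a convention; including them (as here) preserves
  proportional initial loading.
- The shell quantification works on 2D sections/projections; no 3D shell
  segmentation or deconvolution.
- The decay fitter assumes a single exponential over the sampled window;
  extrapolating it far beyond that window misstates the mixture's
  long-time behaviour.
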