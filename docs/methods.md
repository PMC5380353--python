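# Methods

## Image model and energy

The observed image is `I = b·J + n`: a piecewise-constant true image `J`
(one intensity level per region), a smooth strictly-positive multiplicative
bias field `b`, and additive Gaussian noise `n`. Intensities follow the
8-bit 0–255 convention throughout; inputs on [0, 1] are rescaled on load.

Segmentation is encoded by the sign of one level-set function φ (two
phases) or the four sign combinations of a pair (φ₁, φ₂) (four phases).
The smoothed Heaviside `H_ε(φ) = 1/2 + arctan(φ/ε)/π` and its derivative,
the smoothed Dirac `δ_ε(φ) = ε/(π(φ² + ε²))`, make the functional
differentiable; ε sets the width of the transition band around the zero
contour.

The energy couples a *local* data term — the squared difference between `I`
and the bias local fitted image `I_bLFI = b·Σcᵢ Mᵢ` — with a *global* term
using `I_GFI = Σmᵢ Mᵢ`, plus an edge-weighted length term (weight μ) and an
edge-weighted area term (weight ν) built on the edge indicator
`g = 1/(1 + |∇(K_σ∗I)|²)`. Minimization alternates closed-form updates of
the means `mᵢ`, `cᵢ` and the bias `b` with an explicit Euler step on φ in
which both residuals enter as max-normalized signed pressure forces (SPF)
bounded in [−1, 1]; after each step φ is convolved with a Gaussian of std
χ, which regularizes the contour and removes any need for signed-distance
re-initialization. Iteration stops when the sign pattern of φ is
stationary: the fraction of pixels whose sign changed over the last
`check_every = 10` iterations falls to `tol = 1e-4` or below, within
`max_iter = 500` iterations. Non-convergence is reported on the results
object, never raised.

The SPF normalization divides each residual by its maximum absolute value
and then zeroes pixels where `I = 0` exactly, as the force definition
prescribes; a vanished residual yields a zero field and a convergence flag.

## Parameters

Two-phase defaults (`SolverConfig.two_phase()`):

| name | value | meaning |
|------|-------|---------|
| λ₁, λ₂ | 5, 1 | weights of the local-SPF and global-SPF force terms |
| μ | 1 | edge-weighted length (curvature) term |
| ν | 0.25 | edge-weighted area (balloon) term |
| σ | 3 px | fitting-kernel std (local means, bias, edge indicator) |
| χ | 0.5 px | per-iteration Gaussian regularization of φ |
| ρ | 1 | magnitude of the ternary initial level set |
| ε | 1.5 | Heaviside/Dirac width |
| Δt | 1 | explicit time step |

Four-phase defaults (`SolverConfig.four_phase()`): λ₁ = λ₂ = 2, μ = 5,
ν = 0, σ = 3, χ = 0.45, ρ = 1, ε = 1.5, Δt = 1. The curvature term is
active in both four-phase flows (`four_phase_regularity=True`): a nonzero μ
is part of the four-phase constant set and is meaningless otherwise. Two
further fields configure the estimators (below): `crisp_stats=True` and
`bias_smooth=45`.

All Gaussian kernels are truncated at radius ⌈3σ⌉+1, renormalized to unit
sum, and applied with reflective boundary handling. Gradients are central
differences (one-sided at borders), pixel spacing 1. `|∇φ|` in the
curvature term is floored at 1e-8; the bias field is floored at 1e-3
before any division.

## Estimator details and stabilizations

Several aspects of the printed scheme are under-determined or ill-posed on
images with wide uniform regions; the following choices close those gaps.
They were fixed during development against seeded phantom batteries and
then frozen.

**Local-mean form.** The local means smooth the *bias factors*, not the
image: `cᵢ = Σ((K∗b)·I·Mᵢ) / Σ((K∗b²)·Mᵢ)`. With `b ≡ 1` this reduces
exactly to the global means for any kernel width, which is the natural
consistency requirement linking the local and global models.

**Bias initialization.** `b₀ ≡ 1` (neutral gain). The estimate is
refreshed in closed form each iteration, so the initialization only
matters for the first local-mean update — but a degenerate start (`b₀ = 0`)
measurably harms the four-phase solver, which can permanently lose its
smallest region.

**Statistics memberships (`crisp_stats`).** At `|φ| ≈ ρ = 1` with ε = 1.5
the Heaviside products are heavily blended (each four-phase membership is
0.1–0.47 almost everywhere). The closed-form bias update under such
memberships degenerates to an image-follower `b ≈ I/c̄` immediately, which
destroys the identifiability of the means. The four-phase solver therefore
evaluates `mᵢ`, `cᵢ` and `b` on hard sign-based indicators, while the
fitted images and the PDE keep the smooth forms. The two-phase solver
keeps smooth statistics (its single-level-set dynamics do not suffer the
degeneracy), with `crisp_stats` available as a switch — the bias-recovery
configuration uses it.

**Bias smoothness projection (`bias_smooth`).** The kernel-ratio bias
estimate is only determined up to a smooth per-region gauge whenever a
region is much wider than σ = 3: any rescaling `cᵢ → γᵢcᵢ`, `b → b/γᵢ`
inside region *i* is self-consistent, and the alternation drifts through
that gauge freely (local means were observed drifting from 10 to 140 within
ten iterations from exact ground truth). Since the bias is by definition a
broad smooth field, the four-phase solver projects each estimate onto
slowly-varying fields by convolving it with a Gaussian of std
`bias_smooth = 45` px and renormalizing to unit mean. The two-phase default
leaves the projection off (`bias_smooth = 0`), preserving the raw
estimator, whose high flexibility is precisely what absorbs within-object
inhomogeneity; runs aimed at *recovering* the bias field should enable it
at the scale of the expected field.

**Empty phases.** A four-phase membership whose mass falls below 0.02 % of
the image inherits the means of its most massive populated partner (a
partner differs in one level-set sign) rather than the whole-image mean:
the latter installs a fictitious mid-histogram class that noise populates.
With the partner copy, an image with only three true classes leaves the
surplus sign combination empty, as intended. The fitting-module functions
themselves keep the simple image-mean fallback; the substitution is a
solver-level policy.

**Four-phase initialization.** Unless seed regions are given, the image is
clustered into four intensity classes (1-D k-means on raw intensities with
range-spread initial centers; centers closer than 15 % of the intensity
range are merged) and the sorted classes are mapped to the four sign
combinations in binary order. Clustering raw rather than smoothed
intensities avoids manufacturing an intermediate-intensity shell around
sharp edges. The resulting ternary level sets are written at amplitude
`CLUSTER_INIT_AMPLITUDE = 5` — beyond the ε-transition band — because at
amplitude ρ = 1 the blended memberships feed systematically mislabeled
forces that can destroy a correct starting partition within a few
iterations. User-supplied seed regions keep the printed amplitude ρ (or an
explicit `init_amplitude`).

**Sweep order.** Within one four-phase iteration φ₁ is advanced first and
φ₂'s coupling coefficients use the updated φ₁ (Gauss–Seidel); a Jacobi
mode (`sweep="jacobi"`) updates both from the previous iterate and makes
the two level sets exchangeable up to floating-point summation order.

## Synthetic data

The phantom generator realizes `I = b·J + n` at the 250 × 250 working size
with bit-identical regeneration per seed:

* `make_two_region` — one object (default: centered disk, level 170) on a
  background (85), with a linear in-object intensity ramp of relative
  amplitude `inhomogeneity_strength` (at 1 the dim end touches the
  background level) and an optional smooth global bias field.
* `make_combo` — the five object/background homogeneity scenarios,
  including a nested, distinctly-labelled inhomogeneous region inside an
  inhomogeneous object. Background inhomogeneity is a smooth multiplicative
  field (linear profile, relative span 0.35) tapered to 1 near the object
  over ~15 px so the field is smooth everywhere.
* `make_multiregion` — 3- or 4-class piecewise-constant images (disjoint
  disks or brain-like concentric ellipses), a smooth unit-mean bias field
  (broad Gaussian bump or planar ramp) and additive Gaussian noise, clipped
  to [0, 255] (the clip is the one departure from the unbounded model).

What the phantoms do *not* emulate: anatomical geometry, partial-volume
mixing at tissue interfaces, Rician noise statistics, resolution
anisotropy, or any MR acquisition physics. Passing the phantom batteries
therefore demonstrates correctness of the estimators and robustness of the
coupled flows under the stated image model — not clinical-grade brain
segmentation.

## Evaluation

Regions come from strict sign tests on the (optionally mask-scaled) level
sets, so contour pixels and everything outside the mask belong to no
region. Overlap uses the Jaccard index, the Dice coefficient
(`D = 2J/(1+J)`) and the percentage accuracy `100·J`. Since the flow does
not fix which sign labels which tissue, predicted regions are assigned to
ground-truth regions greedily by decreasing Jaccard, making all scores
label-permutation invariant. Two conventions close degenerate cases: two
empty masks compare as perfectly similar (accuracy 100, J = D = 1), with a
warning.

## Known limitations

* **Noiseless perfect fits are ill-conditioned for the SPF.** The
  max-normalization rescales whatever residual remains to ±1, so on exactly
  piecewise-constant images the late-stage forces are amplified fitting
  ripple; boundary-pixel churn can persist and outcomes become sensitive to
  rounding. Realistic sensor noise (σ ≳ 5) regularizes the normalizer and
  makes the four-phase solver markedly more reproducible.
* **Seed basin of the two-phase flow.** The global force carries the small
  local-mean difference (c₁−c₂), so a seed entirely disjoint from the
  object can stall against the area term; seeds that intersect the object
  converge identically regardless of placement.
* **Adjacent extremes.** When the dim end of an inhomogeneous object is
  spatially adjacent to the bright end of an inhomogeneous background and
  the class margins shrink to a few gray levels, the converged contour can
  annex the brightest background pixels.
* **Chaotic sensitivity.** The coupled four-phase flows amplify
  floating-point-level perturbations; runs are bit-reproducible for fixed
  inputs, but permuting the two level sets reproduces the partition only up
  to a small boundary discrepancy.
* 3-D volumes, narrow-band acceleration and GPU execution are out of
  scope; NIfTI input is supported one slice at a time.
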