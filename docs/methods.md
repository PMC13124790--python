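# Methods

`cmrmotus` reconstructs free-running dynamic cardiac MRI by jointly estimating
contrast-varying reference images and low-rank non-rigid motion fields from
undersampled multi-coil k-space. This note documents the model, the solver
choices, the synthetic study generator, and the limits of what the bundled
experiments demonstrate.

## Signal model

A dynamic series `H = [h_1, ..., h_M]` is modelled as a *motion-static but
contrast-varying* reference series `Q = [q_1, ..., q_M]` deformed by per-frame
displacement fields `D_t`:

    h_t(r) = q_t(r + D_t(r)) · det(∇(r + D_t(r)))

The displacements are pull-back displacements (the warped image samples the
reference at `r + D_t(r)`; component order is x-then-y in voxel units), and the
Jacobian-determinant factor expresses conservation of integrated magnetization
under deformation. Each frame is then passed through static complex coil
sensitivities, a unitary 2D FFT, and the per-frame sampling mask:

    s_t = Mask_t · F · C · Warp(q_t, D_t)

All reconstruction acts on Cartesian data; radial acquisitions are gridded to
the Cartesian grid first (nearest-bin averaging), matching how the method was
applied to radial scans.

Two structural priors make the joint problem tractable:

* **Images**: `Q = L + S` with `L` low rank over the Casorati matrix
  (frames × voxels) and `S` sparse under the temporal Fourier transform `T`.
  In all presets the rank of `L` is enforced explicitly (rank 1), so `L` is a
  static backdrop and `S` carries the contrast-agent dynamics.
* **Motion**: `D ≈ Φ Ψᵀ` with an explicit small rank, where the spatial factors
  live on a cubic B-spline control grid (80 control points per direction in the
  default preset) and the temporal factors are per-frame weights, optionally
  parameterized by a temporal cubic B-spline.

## Alternating estimation

Starting from a time-averaged reference (one L+S solve with `D = 0`), the
reconstruction alternates (default 5 rounds):

1. **Motion step** — L-BFGS (memory 10, at most 60 iterations) on
   `Σ_t ‖F(D_t|q_t) − s_t‖² + λ_TV·TV(D)` over `(Φ, Ψ)`, with an analytic
   gradient propagated by the exact chain rule through sampling → FFT → coil
   weighting → warping (including the determinant term, whose finite-difference
   stencils are transposed exactly) → B-spline expansion. `Φ, Ψ` are freshly
   initialized with uniform(−1, 1) random coefficients each round; the spatial
   control grid is band-limited by a Gaussian filter (σ = controls/16) and the
   whole field rescaled so the largest initial displacement is 0.5 voxel.
   Without the band-limiting, white-noise control grids leave O(1) displacement
   gradients in signal-free regions — where the data term has no gradient — and
   those survive optimization and inflate the operator norm of the warp.
   (A warm-start mode, `motion_warm_start`, re-uses the previous round's model
   instead; it anchors the field gauge but was measured to lock in
   early-alternation estimation errors, so it is off by default.)
2. **Re-referencing** — the estimated fields are shifted to a reference motion
   state by subtracting a fixed combination of frames: the temporal mean
   (mid-position, the default) or one designated frame. Fitting always uses
   mid-position; when scoring against ground truth, the estimated fields are
   re-referenced to frame 0 (by subtracting the estimated frame-0 field),
   because the ground-truth fields and the segmentation protocol reference the
   first frame.
3. **Image step** — FISTA on the motion-corrected L+S problem, warm-started
   from the previous `L, S`. The gradient uses the exact adjoint of the warp
   (scatter transpose of the interpolation gather, including the determinant
   weighting and the self-adjoint prefilter). The step size starts at
   `1.3/γ`, with `γ` the largest eigenvalue of `F F*` re-estimated each round
   by a power method (tolerance 1e-4, warm-started with the previous round's
   eigenvector), and is halved whenever the standard quadratic-majorization
   test fails (Beck–Teboulle backtracking); momentum is restarted on objective
   increase. With the `½‖·‖²` gradient convention used here, `1.3/γ` alone is
   ~30% beyond the stability bound, so the safeguard is what makes the stated
   rule usable. The solve stops when the relative objective change stays below
   1e-4 for 4 consecutive iterations, or at the iteration cap (150).

The final cine is `h_t = warp(q_t, D_t)`.

## Parameters and units

* `λ_S` (default 10), `λ_L` (unused under explicit rank), `λ_TV`
  (default 1e-8): regularization weights. Thresholds are `step · λ ·
  lambda_unit`. The published weights carry no unit convention of their own,
  so the package pins them with one conversion factor, `lambda_unit`; the
  default (`"auto"`) is 1e-3 of the peak magnitude of the zero-filled
  time-averaged reconstruction, which places weights of order 1–10 at 0.1–1%
  of the image scale — the operating regime of reference L+S implementations,
  and the regime in which the motion-free baseline reconstructs the moving,
  enhancing heart well (its myocardial SSIM on the bundled phantom matches the
  published baseline value closely). The calibration matters structurally in
  both directions: much stronger thresholds (≥10% of the image scale) leave
  the reference series too biased for the motion step to bootstrap from, while
  the choice of threshold also governs how the motion content splits between
  `S` and `D` (see limitations). A fixed numeric `lambda_unit` overrides the
  automatic scale.
* Rank of `L` and of the motion model: 1 in the default preset (cardiac motion
  only); the other presets use ranks 3–4 with temporal control points 40–150.
* Interpolation: cubic B-spline with a Dirichlet prefilter (image decays to
  zero outside the FOV). The interpolation is exact at voxel centres, so
  `D = 0` reproduces the image bit-for-bit and the model reduces to plain
  masked SENSE sampling.
* Jacobian determinants are computed by centered finite differences of the
  dense fields (one-sided at edges) in all cases — the fields are
  B-spline-smooth, and a single code path keeps the motion-objective gradient
  exactly consistent with its value.
* TV: the default is the standard isotropic total variation per displacement
  component (forward differences, zero-flux boundary), summed over components
  and frames; the printed quadrature-combination variant is available as
  `variant="printed"`. The TV value is exact; its gradient smooths the norm at
  the origin with ε = 1e-7.
* Working precision: single (complex64) for the solvers by default; the
  operator layer follows the dtype of its inputs, and all adjoint/gradient
  verification tests run in double.

## Numerical implementation notes

* Row-structured Cartesian masks (full k-space lines) use a fast path: the
  ky-transform is evaluated only on sampled rows by small per-frame DFT matrix
  products, with the kx FFT applied to the compact rows. The generic
  full-grid masked path computes identical values and serves non-row masks
  (e.g. gridded radial data).
* Inside FISTA the explicit rank truncation uses warm-started orthogonal
  subspace iteration (subspace tolerance 1e-9), numerically equivalent to the
  exact truncated SVD used by the public `hard_rank_truncate`.
* The power method and the `D = 0` initialization are deterministic given the
  configuration seed; the initialization is cached per seed on the model
  object, so fitting the motion-corrected and baseline variants shares it.
* `frequency_split` classifies motion components by the dominant temporal
  frequency of their Ψ columns. Because `D = Φ Ψᵀ` is invariant under any
  invertible R×R mixing, raw-column classification is ill-posed; by default the
  components are first rotated to extremal band purity via the generalized
  eigenvectors of the (low-band, total) energy pair, which is deterministic and
  sign-invariant. `unmix=False` gives the naive behaviour.

## The synthetic study

The generator emulates a free-running 2D short-axis first-pass perfusion
acquisition with the reference acquisition parameters: 600 frames at 50 ms
(one heart beat per 20 frames), 100×100 matrix, saturation-recovery
gradient-echo contrast (Tsat 150 ms, flip 15°, TR 2 ms stored as metadata), 8
ring-placed Gaussian-lobe coils, and pseudo-random Cartesian sampling with 12
readouts/frame (4 fixed central lines plus 8 variable-density random lines
re-drawn per frame, Gaussian ky density as is conventional for
dynamic-contrast L+S sampling; the golden-angle radial scheme with 10 or 20
spokes/frame is available for the radial presets). Anatomy is analytic: body
ellipse filling most of the FOV, myocardial annulus, LV disc, RV crescent.
Tissue carries a band-limited random intensity texture (12 seeded sinusoids,
~6-voxel scale, 5–15% amplitude per compartment) evaluated at the pulled-back
coordinates so it advects exactly with the motion — real tissue is never flat,
and flat regions would leave in-plane motion unidentifiable there. Contrast
kinetics are peak-normalized
gamma-variate boluses (RV onset 5 s, LV 8 s, myocardium 12 s; r1 = 5.0
L·mmol⁻¹·s⁻¹; baseline T1 1650/1100/900 ms for blood/myocardium/body at
1.5 T), converted to signal through the saturation-recovery equation
`M0·sin(flip)·(1 − exp(−Tsat/T1))`.

Motion is specified in closed form as the *pull-back* map from frame-t to
frame-0 coordinates: a raised-cosine systolic radial contraction about the LV
centre (duty cycle 0.4, peak endocardial excursion 3.5 voxels, displacement
profile peaking at the endocardium so the wall thickens during systole),
plus sinusoidal respiratory translation and optional step bulk shifts. Because
the map is closed-form, the ground-truth fields are exact, per-frame labels
are obtained by evaluating the frame-0 indicators at the mapped coordinates
(so labels and fields are consistent by construction), and the frames carry
the analytic Jacobian determinant so the phantom satisfies the model's
magnetization-conservation assumption exactly.

Tissue boundaries are softened over ~1.2 voxels (smoothstep of the signed
distance), emulating partial-volume/band-limited appearance. This matters:
with hard binary edges, gradient-based motion estimation against the
undersampled data is dominated by edge ringing and fails in ways band-limited
data does not.

Noise is complex Gaussian on the sampled k-space points, by default at 30 dB
sample SNR.

What the phantom does *not* emulate: through-plane motion and its violation of
in-plane magnetization conservation, realistic tissue texture, B0/B1
inhomogeneity, bSSFP banding, k-space trajectory imperfections, and the
ECG/respiratory variability of real free-running exams. Passing the bundled
experiments therefore demonstrates correctness of the estimation machinery
under the model's own assumptions, not clinical performance.

## Scaled-down study sizes

The bundled end-to-end experiments run the 100×100 study at 200 frames (10 s,
ten heart beats, covering the RV/LV inflow) rather than the full 600, and the
recovery/disentanglement experiments use 48–64 voxel grids; these sizes retain
the behaviour of interest while keeping the full test suite and the
acceptance script at desk scale. `scripts/acceptance.py` re-runs all of them
from scratch.

## Known limitations

* The motion model is unconstrained where the image carries no signal;
  displacement estimates there are meaningless (and are excluded from the
  reported masked metrics). Strong over-regularization would hide, not fix,
  this identifiability gap.
* The determinant factor lets extreme deformations mimic intensity changes;
  with heavily undersampled data and a poor current Q the early alternations
  can produce locally folded fields (negative determinants). No diffeomorphic
  guarantee exists.
* **The reference/motion factorization is gauge-ambiguous**: many (Q, D) pairs
  compose to the same cine, and only the regularization decides how motion
  splits between the sparse image component and the fields. On the bundled
  undersampled study the reconstruction reliably improves the *cine* (the
  image-similarity comparison reproduces the published direction and values),
  but the *fields* retain a non-identified component of roughly two voxels:
  fresh random restarts re-draw it every alternation, and warm starts freeze it
  instead of removing it. Motion-field accuracy metrics (EPE, warped-
  segmentation DICE) should therefore be read with care at this undersampling;
  with fully sampled data the motion step recovers fields to ~0.1 voxel.
* Convergence of the alternation is iteration-count based (no outer
  tolerance), following the reference procedure.
* 2D only; no through-plane motion; no ESPIRiT coil estimation (maps are
  inputs; the phantom's are analytic).
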