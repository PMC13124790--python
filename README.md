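# cmrmotus

Joint reconstruction of **non-rigid motion fields** and **contrast-varying
images** for free-running dynamic cardiac MRI (CMR-MOTUS-style alternating
estimation).

First-pass myocardial perfusion exams mix several dynamics — cardiac and
respiratory motion, bulk shifts, and the inflow of a gadolinium bolus — and
free-running (untriggered, free-breathing) acquisitions see all of them at
once. Reconstructing such data frame-by-frame from a handful of k-space lines
is hopeless without structure. This package implements a joint model that
splits the dynamics by their nature:

* the image content is a low-rank-plus-sparse series `Q = L + S` (`L`: static
  anatomy, rank-constrained; `S`: contrast enhancement, sparse under the
  temporal Fourier transform `T`);
* the motion is an explicit low-rank field `D ≈ Φ Ψᵀ` on cubic B-spline
  control grids, entering the MR signal model through a determinant-weighted
  pull-back warp `h_t(r) = q_t(r + D_t(r)) · det(∇(r + D_t(r)))`.

Two sub-problems are solved alternately for a fixed number of rounds:

    step 1 (images):  min_{L,S}  Σ_t ½‖F(L_t+S_t | D_t) − s_t‖² + λ_L‖L‖_* + λ_S‖TS‖₁
    step 2 (motion):  min_{Φ,Ψ}  Σ_t ‖F(D_t | q_t) − s_t‖² + λ_TV TV(D)

step 1 by FISTA (step `1.3/γ` with `γ` from a power method, backtracked),
step 2 by L-BFGS with an exact analytic gradient through the warp and B-spline
expansion. The package also ships an analytic first-pass-perfusion phantom
with exact ground-truth motion, segmentations and enhancement curves, and the
validation metrics used to score reconstructions (SSIM, end-point error,
DICE of warped segmentations, Tenengrad sharpness). It is aimed at MR
reconstruction researchers who want a self-contained, testable reference of
the method.

## Worked example

```python
from cmrmotus import CMRMotus, ReconConfig
from cmrmotus.phantom import PhantomConfig, simulate

# synthetic free-running perfusion study: 100x100, 8 coils, 12 Cartesian
# lines/frame; 200 frames = 10 s = ten heart beats with RV/LV bolus inflow
kspace, coil_maps, truth = simulate(PhantomConfig(n_frames=200, seed=1))

model = CMRMotus(kspace, coil_maps, ReconConfig(seed=1))
result = model.fit()                      # alternating CMR-MOTUS
baseline = model.fit(method="lps")        # same settings, no motion (D = 0)

print(result.summary())
scores = result.evaluate(truth)
print("SSIM (myocardium):", round(scores["ssim_myocardium"]["mean"], 4))
print("DICE warped myocardium:", round(scores["dice_warped"]["mean"], 4))
print("EPE (myocardium):", round(scores["epe_myocardium"]["mean"], 3), "voxels")
```

`result.summary()` prints a per-alternation table (step sizes `γ`, FISTA
iteration counts, objective values); `evaluate` scores the cine against the
phantom's noiseless frames and exact motion fields. On this phantom the run
above gives a myocardial SSIM of 0.976 for the motion-corrected cine against
0.971 for the motion-free L+S baseline — motion inclusion improves image
similarity, the direction (and nearly the values) of the reference in-silico
comparison. The estimated *fields* are less identifiable at this
undersampling: the warped-segmentation DICE stays below the registration-free
overlap (see the gauge-ambiguity discussion in `docs/methods.md`).

The same objects drive the command line:

```bash
cmrmotus simulate --preset test1 --seed 7 -o data.h5
cmrmotus recon --method motus --preset test1 -i data.h5 -o recon.h5
cmrmotus evaluate -i recon.h5 --truth data.h5 -o metrics.json
```

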