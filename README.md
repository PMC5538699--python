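# ventprofile

Thoracic electrical impedance tomography (EIT) estimates regional lung
ventilation from surface voltage measurements, but the reconstructed images
depend strongly on the reconstruction model and its settings.  `ventprofile`
implements the full comparison pipeline for that question: how much does
embedding anatomical information — the true thorax contour, organ
conductivity weighting, lung-pixel masks — improve the accuracy of
anteroposterior ventilation distribution profiles?

It is written for EIT methods researchers.  The package contains

* a **complete-electrode-model FEM forward solver** on deterministic 2.5D
  extruded meshes with 32-electrode skip-4 stimulation (3 mA; 928 valid
  channels of 1024) and adjoint sensitivities,
* **GREIT** training (target size *ts*, weighting radius *rw*, uniform or
  lungs-0.2/heart-1.5 weighted background, TD/NTD referencing) and one-step
  regularized **Gauss-Newton** (Tikhonov / Laplace / NOSER priors), both with
  the regularization level calibrated by bisection to a requested **noise
  figure** *nf*,
* the **recording pipeline**: voltage referencing, frame-wise reconstruction,
  breath-phase detection, breath-averaged tidal images ΔZ, 10%-of-maximum
  thresholding or lung-mask selection,
* **evaluation statistics**: 32-band anteroposterior profiles *vd*
  (normalized to 100%), per-subject profile RMSE, pooled Pearson correlation,
  non-parametric Bland–Altman (median bias, 2.5th–97.5th percentile limits),
  Kruskal–Wallis with Tukey–Kramer rank-sum post-hocs, and rank-aggregated
  reconstruction-settings sweeps,
* a **synthetic thorax-phantom simulator** (circular / averaged /
  individualized pig-like geometries; 6 breaths·min⁻¹ at 48 Hz for 30 s,
  1,440 frames; lung conductivity modulation with an anteroposterior
  gradient; measurement noise; inverse-crime-free refined simulation meshes)
  that also emits the ground-truth tidal aeration image and profile playing
  the role of a reference CT.

The central quantity is the anteroposterior ventilation profile: the tidal
image is summed in 32 horizontal bands from ventral to dorsal and normalized,

    vd_i = 100% · Σ_{pixels in band i} ΔZ / Σ_{all masked pixels} ΔZ ,

and model variants are scored by RMSE(vd_EIT, vd_ref) across subjects.

## Worked example

Simulate one subject, train an individualized GREIT model, and score the
lung-masked profile against the ground truth:

```python
from ventprofile import (
    BreathingConfig, GreitConfig, PhantomConfig,
    make_phantom, simulate_recording, build_model,
    process_recording, lung_select, ap_profile, profile_rmse,
)

geometry = make_phantom(PhantomConfig(kind="individual", seed=0))
recording, truth = simulate_recording(
    geometry, BreathingConfig(sim_target_elements=12000))
model = build_model(geometry, GreitConfig(nf=0.5), target_elements=6000)
print(f"calibrated lambda = {model.lam:.3g}, achieved nf = {model.achieved_nf:.4f}")

tidal, markers, _ = process_recording(
    model.matrix, recording, nominal_breath_period=10.0)
print(f"breaths detected: {markers.n_breaths}")

vd = ap_profile(lung_select(tidal, model.grid).pixels, model.grid.lung_mask)
print(f"profile RMSE vs ground truth: "
      f"{profile_rmse(vd, truth.vd_truth):.2f} percentage points")
print("posterior-half ventilation: "
      f"EIT {vd.values[16:].sum():.1f}%  truth {truth.vd_truth.values[16:].sum():.1f}%")
```

This prints:

```
calibrated lambda = 0.327, achieved nf = 0.5000
breaths detected: 3
profile RMSE vs ground truth: 1.04 percentage points
posterior-half ventilation: EIT 80.1%  truth 77.6%
```

The regularization weight was chosen automatically so that the
reconstruction's noise figure matches the requested 0.5 (to 0.01%); the
30-second recording contains its three breaths; and the individualized,
lung-masked profile tracks the posterior-weighted ground-truth distribution
to about one percentage point per band.

The cohort-level experiment — eight phantoms, reconstructed with the
circular (vd¹), averaged (vd², vd²⁺) and individualized (vd³, vd³⁺) priors
and compared by Kruskal–Wallis — is one call
(`ventprofile.model_comparison(ventprofile.cohort(n=8))`) or, from the
shell, `ventprofile evaluate --seed 0 --out runs/eval`.  The CLI also
exposes `phantom`, `simulate`, `train`, `reconstruct`, `profile` and
`sweep`; every command takes a TOML `--config`, a `--seed`, and writes its
outputs plus a manifest under `--out`.

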