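# vtexit

Simulation-driven localization of post-infarct ventricular tachycardia
(VT) exit sites from the 12-lead ECG and implanted-device electrograms
(EGMs).

Catheter ablation of post-infarct VT hinges on finding the circuit's
**exit site** — the point where the re-entrant wavefront leaves the
protected isthmus between scar regions and captures healthy myocardium,
i.e. the site of earliest systolic activation. Invasive electroanatomic
mapping localizes it well but requires inducing and sustaining the
arrhythmia. `vtexit` is a computational platform for the non-invasive
alternative: learn the inverse map from a beat's extracellular signals
(surface ECG, or the EGM sensing vectors already stored by implanted
devices) back to its source location, using simulated beat libraries as
training data. It is aimed at computational electrophysiologists and
ML-for-cardiology researchers who want a self-contained, fully seeded
sandbox for this localization problem.

## What it does

- **Anatomy** — parametric thick-walled ventricles (truncated
  prolate-ellipsoid shells) with rule-based transmural fiber rotation
  (+60° endo → −60° epi), labelled surfaces, and template-placed surface
  and device electrodes; cohorts of virtual patients by geometric
  perturbation.
- **Activation** — anisotropic graph-eikonal solver (edge traversal time
  `|e| / (mult · v(θ))`, `v(θ) = sqrt((v_l cosθ)² + (v_t sinθ)²)`) plus
  action-potential-template synthesis of transmembrane traces.
- **Forward model** — infinite-volume-conductor pseudo-ECG collapsed to
  per-anatomy lead-field matrices; standard 12-lead ECG + 4 vector
  combinations, and 8 device EGM sensing vectors, all reference-invariant.
- **Substrate** — two inexcitable scar lobes framing a slow-conduction
  isthmus in UVC space; VT beats as systolic activations from the
  corridor exit, with circuit cycle-length metadata.
- **UVC** — universal ventricular coordinates `(z, ρ, φ)` (apicobasal,
  transmural, rotational), 17-AHA-segment reporting, and the
  localization-error metric LE = ‖x_pred − x_true‖ in mm.
- **Localizer** — a 1-D convolutional encoder + dense head regressing
  `(z, ρ, sin φ, cos φ)`, trained on paced beats and transfer-fine-tuned
  on VT beats with exact freeze policies.
- **Evaluation** — the two rotating held-out scenarios ("seen during
  pacing training" vs "fully unseen" anatomy) with leakage audits and
  per-torso / pooled LE statistics.

See `docs/methods.md` for the models, assumptions, and limitations.

## Worked example

`examples/` contains one narrative script per capability. Training the
localizer end-to-end at toy scale (`python examples/04_train_localizer.py`):

```
simulated 240 paced and 32 VT beats
base training: val loss 0.0731 after 25 epochs
transfer (encoder frozen): val loss 0.0790
VT beat anat00_v0002: predicted exit in AHA segment 9 (true 9), localization error 7.8 mm
```

The losses are MSE over the scaled UVC targets; the last line shows a
held-back VT episode whose exit site the model places in the correct
AHA segment, 7.8 mm from the true exit — at this toy scale (240
training beats) already inside the ≤ 17 mm band considered useful for
seeding ablation pre-planning. Simulating a substrate directly
(`python examples/03_vt_substrate.py`):

```
scar centered in AHA segment 10 at z=0.54, phi=-2.16 rad; isthmus multiplier 0.25
exit site: node 1258, UVC (z=0.70, rho=0.52, phi=-2.18) -> AHA segment 4
circuit cycle length: 266 ms
systolic activation: 2901 nodes in 205 ms; 42 scar nodes never activate
```

The 266 ms cycle length (corridor transit + return around the scar) sits
in the clinically typical range, and the scar lobes never activate.

A thin CLI mirrors the pipeline stages:

```bash
vt-exitsite make-anatomy --out anat/
vt-exitsite simulate-pacing --out lib/paced
vt-exitsite simulate-vt --out lib/vt
vt-exitsite train --mode ecg --pacing-lib lib/paced --vt-lib lib/vt --out model/
vt-exitsite evaluate --scenario 1 --mode ecg --out results/
vt-exitsite run-all --out results/        # everything, with stage caching
```

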