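# pulse4d

Quantification of intracranial aneurysm pulsation from ECG-gated 4D CT
angiography (4D-CTA), with a pulsation-plausibility statistic and
observer-agreement analysis — validated end-to-end on a synthetic
pulsating-aneurysm phantom with analytic ground truth.

## The problem

Whether an unruptured aneurysm pulses over the cardiac cycle may carry
information about its wall and rupture risk, but the wall excursions are at
or below the CT voxel size, so naive voxel counting measures mostly noise.
`pulse4d` implements a sub-voxel measurement chain for people working on
4D-CTA post-processing:

- **threshold lumen segmentation** (160–890 HU) per cardiac phase, with VOI
  cropping and seeded connected-component clean-up;
- a **3D+t surface model**: marching-cubes isosurface of the grayscale HU
  field per phase, enclosed volume by the divergence theorem
  (V = ⅙ Σ v₀ · (v₁ × v₂) over triangles);
- **neck transfer** of phase-0 neck points to all phases by rigid ICP
  (nearest-neighbour correspondences + closed-form Kabsch alignment),
  a **cut surface** fanned over the transferred points, and region-grown
  dome/vessel **partition** giving the per-phase aneurysm volume V(p);
- the **pulsation statistic**: min-max normalize V(p), compute the symmetric
  Hausdorff distance d(V, w) to an arterial pulse-wave template w, and
  compare against distances of random noise curves (Gaussian, mean 0.5,
  SD 0.2) with a Welch t-test — pulsatile curves sit significantly closer
  to the pulse wave than noise does;
- **pulsation amplitude** A = Vmax / Vmin, and **agreement statistics**
  (Bland–Altman bias ± 1.96·SD limits, ICC(2,1)/ICC(3,1) with the
  "ICC > 0.75 is good" rule, Spearman correlation, Welch t-test);
- a **phantom generator**: sphere-on-tube aneurysm whose dome volume follows
  the pulse template exactly (amplitude known to 1e-9), rasterized at
  0.39 × 0.39 × 0.5 mm with PSF blur and 18% lumen noise — the acquisition
  conditions all validation runs use.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
from pulse4d import (PhantomSpec, generate_phantom_4d, generate_pulse_template,
                     generate_random_null, cohort_pulsation_report,
                     pulsation_amplitude)
from pulse4d.experiments import measure_volume_curve

# an 8.5 mm aneurysm pulsating at amplitude 1.06 under 18% image noise
spec = PhantomSpec(pulsation_amplitude=1.06, noise_fraction=0.18, seed=42)
vol, truth = generate_phantom_4d(spec)

res = measure_volume_curve(vol, truth)          # full pipeline
print(np.round(res.volumes, 1))
print("amplitude:", round(pulsation_amplitude(res.curve), 3))

pulse = generate_pulse_template(spec.n_phases)
null = generate_random_null(14, spec.n_phases, seed=42, pulse=pulse)
rep = cohort_pulsation_report([res.curve], pulse, null)
print("distance to pulse wave:", round(float(rep.distances[0]), 3),
      "| null mean:", round(rep.mean_null, 3), "| p:", f"{rep.p:.2g}")
```

prints

```
[254.8 262.6 268.8 264.7 260.  258.1 257.1 255.6 252.7 252.8]
amplitude: 1.064
distance to pulse wave: 0.108 | null mean: 0.505 | p: 8.6e-10
```

The ten values are the per-phase aneurysm volumes in mm³: the early-systolic
rise and diastolic decay follow the pulse template. The measured amplitude
(1.064, true 1.06 under this noise draw) and the small Hausdorff distance
relative to the random-noise null (0.11 vs 0.50) are what mark this curve as
pulsatile rather than noise.

The same chain is scriptable from the shell:

```sh
pulse4d phantom --out phantom.nii.gz --truth truth.json
pulse4d segment --in phantom.nii.gz --out mask.nii.gz --low 160 --high 890
pulse4d separate --in phantom.nii.gz --neck neck.csv --seed-point 9.17,9.17,10.9 \
                 --iso 220 --out curve.csv
pulse4d pulsation --curves curve.csv --null-n 14 --seed 42 --out report.json
```

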