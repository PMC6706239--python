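# dynamrs

Dynamic ¹³C magnetic-resonance spectroscopy and spectroscopic imaging
analysis **without hyperpolarization**: low-rank noise suppression, NMR
spectral preprocessing, and metabolic kinetic modelling for glucose-bolus
experiments in tumor-bearing animals, plus the classical two-pool analysis of
hyperpolarized [1-¹³C] pyruvate.

## Who this is for

Directly detecting a [U-¹³C] glucose bolus and its conversion to lactate by
¹³C MRS is attractive — no radiotracer, no dissolution-DNP polarizer, access
to metabolism *downstream* of uptake — but the raw signal is close to pure
noise.  `dynamrs` implements the processing chain that makes it work: the
strong temporal/spectral/spatial redundancy of a dynamic acquisition is
exploited by truncated-SVD (2-D series) and Tucker/HOOI (4-D chemical-shift
imaging) low-rank reconstruction, and the cleaned signal is fit with simple
first-order kinetic models to produce glucose-utilization and
lactate-formation rates, voxel-wise rate maps, and group statistics.

Everything is testable offline: the `synthetic` module generates dynamic FID
series, CSI k-space tensors and pyruvate decay series with known ground
truth.

## The models

**Glucose (piecewise, C1 resonance at 98 ppm, times in minutes).**
Transport/perfusion during the bolus (t < t₀ ≈ 5 min):

    S(t) = S_total (1 − B e^(−k_trans t))

After complete bolus passage (t > 5 t₀ ≈ 25 min), parallel first-order losses
(metabolism + clearance); the *utilization* rate is their sum:

    S(t) = A e^(−k_util t),   k_util = Σᵢ kᵢ

Lactate (23 ppm) has no transport term and follows the saturating rise
`L(t) = L_max (1 − e^(−r t))`; `r` is the *formation* rate.

**Hyperpolarized pyruvate (two-pool unidirectional flux, equal effective
relaxation, Lac(0) = 0, times in seconds):**

    Pyr(t) = Pyr(0) e^(−(k + 1/T₁) t)
    Lac(t) = Pyr(0) (e^(−t/T₁) − e^(−(k + 1/T₁) t))

The apparent pyruvate decay rate is exactly `k + 1/T₁`, and the
lactate/pyruvate AUC ratio converges to `k·T₁` for long acquisitions.

**Low-rank denoising.**  A dynamic series reshaped as a frames × frequency
Casorati matrix is replaced by its best rank-r approximation (r = 5 by
default, the Eckart–Young truncated SVD).  A 4-D CSI tensor
(x × y × spectrum × time) is compressed by higher-order orthogonal iteration
(HOOI) to multilinear ranks (6, 6, 8, 8).

**Preprocessing.**  Receiver dead time corrupts the first 67 of 256 FID
points; they are removed and later *restored by backward linear prediction*
(the time-origin shift is not representable as a first-order phase ramp at
78 Hz per bin).  Forward–backward LP with root reflection extends each frame
to 1024 points, spectra are phased by entropy minimization with a
negative-area penalty, and baselines are estimated by a first-derivative
(Dietrich-style) mask followed by a Whittaker smoother.

## Worked example

```python
import numpy as np
from dynamrs import RunConfig
from dynamrs.io import run_pipeline

cfg = RunConfig(seed=3, csi_n_frames=50, duration_s=1800.0,
                frame_spacing_s=30.0, noise_sigma=30.0)
report = run_pipeline(cfg, "simulate", "results/run")
print(round(report["fits"]["glucose_utilization"]["k_util_per_min"], 4))
print(round(report["fits"]["glucose_uptake"]["k_trans_per_min"], 3))
print(round(report["maps"]["glucose_rate_median_per_min"], 4))
print(report["truth"])
```

prints

```
0.0202
0.802
0.0204
{'k_util_per_min': 0.02, 'k_trans_per_min': 0.8, 'lac_rate_per_min': 0.05}
```

i.e. from a noisy simulated bolus experiment (spectral noise sd 30 against
per-voxel peak signals of ~100 a.u. summed over 64 voxels) the pipeline
recovers the programmed glucose utilization rate of 0.02 min⁻¹ within 1%
from the non-localized series and within 2% as the median of the voxel-wise
CSI rate map, and the transport rate 0.8 min⁻¹ within 0.3%.

The same stages are scriptable from the shell:

```bash
dynamrs simulate --seed 3 --out container.h5
dynamrs preprocess container.h5 --out spectra.h5
dynamrs denoise container.h5 --out denoised.h5
dynamrs map denoised.h5 --metabolite glucose --out rates.csv
dynamrs stats metabolites.csv --group-a s1,s2,s3 --group-b s4,s5,s6
```

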