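# Methods

This note records the models implemented in `dynamrs`, the assumptions they
make, the defaults and why, and the design choices taken where several
reasonable options existed.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and synthetic data

The simulators emulate a pulse-acquire dynamic ¹³C experiment at 9.4 T:
256 complex FID points, 198.6 ppm sweep width at a 100.65 MHz carrier
(dwell ≈ 50 µs, ~78 Hz per 256-point bin), TR 50 ms, 12° excitation,
16 averages per stored frame, and 67 dead-time points.  Spectra contain the
glucose C1 anomers at 98/95 ppm (β:α amplitude 64:36), a large constant
lipid resonance at 32 ppm, lactate at 22.8 ppm and alanine at 18.9 ppm.
Lorentzian linewidths default to 50 Hz (glucose), 80 Hz (lipid) and 40 Hz
(lactate/alanine): in vivo shim quality plus the unresolved ¹³C–¹³C
couplings (~45 Hz) of a uniformly labelled tracer make narrower lines
unrealistic.  The short-TR saturation bias is a static per-metabolite
amplitude factor (`relative_t1_weight`), not a Bloch simulation — it skews
apparent concentrations, never fitted rates.

Kinetic time courses: glucose follows the transport rise
`S_total(1 − B e^(−k_trans t))` for t < t₀ = 5 min and the utilization decay
`S_total e^(−k_util t)` for t > 5t₀ = 25 min; the bolus-passage window in
between is bridged linearly because every fit excludes it.  Lactate and
alanine follow `A(1 − e^(−rt))`, the simplest monotone appearance model
consistent with observed traces.  Default rates (tumor tissue):
k_trans = 0.8 min⁻¹, k_util = 0.02 min⁻¹, lactate formation 0.05 min⁻¹,
with amplitudes s_total = 100, lactate 30, alanine 10, lipid 200 (the
dominant peak).  `tumor_phantom` provides a spatially heterogeneous variant
(disk-shaped tumor, smooth radial amplitude, k_util 0.01→0.04 min⁻¹ left to
right with an anti-correlated lactate gradient) emulating locally varying
glycolysis in a necrotic xenograft.

Noise is i.i.d. circular complex Gaussian, parameterized by the standard
deviation of the *real part of the spectrum* per bin (`noise_sigma`); CSI
noise is added in k-space with the variance scaled so the reconstructed
image-domain spectra carry the same per-bin sd.  Phase errors
(zero/first-order) and a smooth Chebyshev baseline are applied in the
frequency domain.

What the generator does **not** emulate: coil sensitivity profiles and
correlated multi-channel noise, B₀ drift and per-voxel frequency shifts,
chemical-exchange or J-modulation lineshape effects, motion, and partial
volume at the tumor boundary.  Passing tests therefore demonstrate
correctness of the algorithms under the stated signal model, not robustness
to every artifact of real animal data.

## Preprocessing chain

Order: truncate dead time → SVD denoise → restore head by backward LP →
forward LP extension → FT → entropy phasing → Whittaker baseline.

* **Dead time.**  The first 67 points are removed.  Because the resulting
  time-origin shift corresponds to a first-order phase ramp of ~121°/ppm —
  wrapping ~94° *per spectral bin* at this digitization — it cannot be
  undone by a (phase0, phase1) correction.  Instead the missing head is
  synthesized by backward linear prediction: signal poles are estimated from
  the surviving points (forward–backward equations on the frame-averaged
  FID, roots reflected inside the unit circle), per-frame complex amplitudes
  are fitted by least squares, and the pole model is evaluated at negative
  time indices.  Only poles decaying no faster than a 200 Hz linewidth may
  extrapolate backward; faster (noise) poles grow without bound as
  `|z|^(−67)`.
* **Linear prediction.**  Forward extension 189 → 1024 points uses the same
  forward–backward estimator, default order 16 (≈ n/12, comfortably above
  twice the simulated component count).  Coefficients are estimated once
  from the frame-averaged FID (`shared_poles=True`): every frame contains
  the same resonances, and per-frame estimation at realistic noise produces
  near-unit-circle noise poles whose extensions corrupt the spectrum.
* **Phasing.**  Entropy minimization: Shannon entropy of the normalized
  |first derivative| of the real part plus a quadratic negativity penalty
  (weight 10⁴), with negativity judged against the spectrum median — the
  DFT of a one-sided FID carries a positive offset that would otherwise
  mask the dispersion lobes the penalty exists to punish.  Nelder–Mead from
  8 zero-order starts, ties broken by smallest |phase0|.  On noiseless
  well-resolved three-peak spectra the minimum sits within ~1° / ~0.06°⋅ppm⁻¹
  of the true phases; the surface has a shallow ridge along the first-order
  direction.  An optional apodized estimation copy (`broaden_bins`) exists
  for spectra whose lines span ≲ 1 bin.
* **Baseline.**  Dietrich-style first-derivative mask: smoothed (5-bin)
  squared derivative thresholded at median + 3·1.4826·MAD with the
  statistics re-estimated iteratively on sub-threshold bins, an absolute
  floor of 10⁻⁶ × max for noiseless input, morphological opening (8 bins) to
  reject smoothing-correlated noise runs with an amplitude rescue
  (> 25 × threshold) for strong narrow peaks, and dilation by 3 × the
  estimated FWHM (capped at n/10) to exclude Lorentzian tails.  Calibrated
  so pure-noise spectra keep ≥ 95 % of bins as baseline.  The baseline
  itself is the weighted Whittaker smoother (second-difference penalty,
  λ = 10⁷ by default) fitted to masked bins only; correction subtracts it
  from the real part.  Baseline correction runs *last* — subtracting a
  real-valued curve creates an anticausal mirror component that would break
  the causal pole model had LP run afterwards.

## Low-rank reconstruction

`SVDDenoiser` (matrix rank 5) and `TuckerDenoiser` (HOOI, ranks 6, 6, 8, 8
for x, y, spectrum, time; HOSVD initialization; ≤ 50 sweeps; stop when the
relative change of explained norm < 10⁻⁶) follow the scikit-learn
transformer protocol and operate on complex arrays.  The explained norm is
non-decreasing across sweeps by construction of the alternating mode-wise
SVD updates.  Denoising is applied to complex data; because the DFT is
unitary along any one mode, denoising the time-domain or frequency-domain
representation gives identical reconstructions up to that transform, and
the pipeline denoises FIDs before transforming.  Rank selection is fixed at
the protocol values; no data-driven rank heuristic is applied by default.

## SNR benchmark and its ceiling

SNR is defined project-wide as (max |signal| in the peak window) / (sd of
the real part in a signal-free window), pooled over frames (and voxels for
tensors).  The benchmark protocol (`dynamrs.protocols.csi_snr_gain`, also
run by `scripts/acceptance.py`) simulates the 8×8×256×75 heterogeneous-tumor
CSI acquisition with noise calibrated so the median tumor voxel has
per-frame peak SNR ≈ 2, denoises by HOOI at ranks (6, 6, 8, 8), and reports
the median after/before SNR ratio over 10 seeds.

The dof arithmetic sets the scale of what such a benchmark can show: an
oracle projection onto fixed rank-(6, 6, 8, 8) subspaces retains a fraction
`(6·6·8·8)/(8·8·256·75) ≈ 1.05×10⁻³` of white-noise variance — a noise-sd
reduction of ~30.8×.  The *measured* after/before peak-SNR ratio is
necessarily smaller, for two reasons quantified in the test suite: (i) at
input peak SNR 2 the signal's spectral rank (~2 resonances) is far below the
retained spectral rank 8, so the remaining HOOI dimensions adapt to the
largest noise directions and inflate the retained noise sd roughly
threefold over the oracle bound; (ii) the raw "peak max" numerator is
dominated by the maximum of ~10⁶ noise draws (≈ 4.6 σ) rather than the 2 σ
signal.  Under this white-noise model the measured median gain is ~6; the
script reports whatever it computes.

## Imaging

Rectilinear phase encoding acquires the spatial DFT directly, so
reconstruction is symmetric k-space zero-filling (8×8 → 16×16 for display)
followed by an inverse 2-D DFT, with amplitudes rescaled so voxel values do
not depend on the reconstruction grid.  Voxel geometry (0.3 × 0.3 × 1.5 cm
acquired; half-size in-plane after zero-filling) is carried as metadata
only.  Voxel spectra are processed in magnitude mode — voxel-wise phase
estimation is unreliable at this SNR — and the Rician noise floor is removed
by subtracting the per-frame median of a signal-free window (150 ± 15 ppm by
default) before integration.  Rate maps fit the utilization decay (glucose,
t > 25 min) or the formation rise (lactate) per voxel; voxels whose peak SNR
falls below 5 are masked rather than fitted (the max-over-window statistic
of pure noise concentrates near 4 σ, so a threshold of 3 would mask
nothing).  Contour maps take the per-voxel window maximum at one frame or
averaged over frames.

## Kinetic fitting

All fits are bounded trust-region least squares with three data-derived
starts (ties: lowest residual, then smallest rate); 95 % confidence
intervals come from the asymptotic covariance of the Jacobian.  Perfectly
flat utilization traces return rate 0 exactly and are flagged; B < 10⁻³
flags k_trans as unidentifiable.  The two-pool pyruvate fit is joint over
both traces with parameters (Pyr₀, k, T₁); the reported decay rate is the
identity k + 1/T₁.  A variant of the two-pool model circulating in the
literature scales both pools by k; the implemented default is the
mass-balanced solution with Lac(0) = 0 (the exact ODE solution), and
`k_scaled_form=True` reproduces the k-scaled variant for comparison.

Known limitation: the decay and rise models carry no additive-offset term,
so residual baseline or dispersion leakage (e.g. the lipid tail under the
lactate window, or uncorrected zero-order phase of ~25°) biases fitted
rates — up to ~30 % for k_util under a 25° phase error and more for the
lactate formation rate, while leaving trace shapes (correlation ≈ 1) and
rate *orderings* intact.  Rates from well-phased data recover truth to ~1 %.

## Statistics

`mann_whitney` delegates to the exact-enumeration path for combined n ≤ 12
without ties and the tie-corrected normal approximation otherwise (two-sided
by doubling, capped at 1).  `cohens_d` uses the pooled (n−1)-denominator sd.
`two_stage_stepup_fdr` implements the two-stage linear step-up procedure:
stage 1 runs a step-up pass at q′ = q/(1+q), the null count is estimated as
m₀ = m − r₁, and stage 2 re-runs the step-up at q′·m/m₀; a Holm step-down
option is provided for familywise control.  Missing values are dropped
pairwise per feature.  Note the two-stage pass is *generically*, not
universally, at least as powerful as plain BH at the same q — knife-edge
p-vectors exist where q′·m/m₀ < q; the property test uses generic spiked
inputs.

## Problem sizes

Defaults used by the tests and the benchmark: 8×8 CSI grids with 40–75
frames, non-localized series of 60–225 frames, 100-replicate noise studies
for parameter recovery, 2000-replicate null studies for FDR calibration.
These sizes make every conclusion reproducible on a laptop in minutes while
keeping Monte-Carlo errors a factor of a few below the tolerances tested.
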