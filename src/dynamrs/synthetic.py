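"""Synthetic dynamic :sup:`13`\\ C data with known ground truth.

Everything downstream — preprocessing, low-rank denoising, kinetic fitting,
rate mapping — is validated against phantoms generated here.  The forward
model mirrors the in vivo protocol:

* non-localized dynamic FID series (256 complex points, 198.6 ppm sweep,
  TR 50 ms, 12 degree excitation, 16 averages per stored scan) carrying the
  glucose C1 anomer peaks near 98/95 ppm, lactate at 22.8 ppm, alanine at
  18.9 ppm and a large static lipid resonance at 32 ppm;
* 8 x 8 rectilinear phase-encoded CSI frames every 48 s;
* hyperpolarized [1-13C] pyruvate decay series.

Glucose amplitude follows the piecewise kinetic model: an exponential
transport rise ``S_total (1 - B exp(-k_trans t))`` before the bolus has
passed (t < t0), a first-order decay ``S_total exp(-k_util t)`` after
complete passage (t > 5 t0), and a linear bridge in between (the bridge is
excluded from every fit window, so its exact shape is immaterial).  Lactate
and alanine follow a saturating rise ``A (1 - exp(-r t))``; the lipid peak is
constant.

Pyruvate/lactate follow the two-pool unidirectional flux model with equal
effective relaxation times and Lac(0) = 0::

    Pyr(t) = Pyr(0) exp(-(k + 1/T1) t)
    Lac(t) = Pyr(0) (exp(-t/T1) - exp(-(k + 1/T1) t))

Noise is i.i.d. circular complex Gaussian, calibrated so that the standard
deviation of the *real part of the spectrum* in a signal-free region equals
``noise_sigma``.  Unknown zero/first-order phase errors and a smooth
Chebyshev baseline distortion are applied in the frequency domain.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    AcquisitionParams,
    CSIDataset,
    FIDSeries,
    KineticTrace,
    PeakBasis,
    PhantomTruth,
)

__all__ = [
    "DEFAULT_PEAKS",
    "PYRUVATE_PEAKS",
    "glucose_amplitude",
    "saturating_rise",
    "pyruvate_signal",
    "lactate_signal",
    "make_phantom",
    "simulate_glucose_series",
    "simulate_csi",
    "simulate_pyruvate_series",
    "tumor_phantom",
    "lorentzian_fid",
    "synthetic_spectrum",
]

#: Peak basis for the glucose-bolus experiment.  Linewidths reflect in vivo
#: 13C conditions (B0 inhomogeneity plus unresolved 13C-13C couplings of the
#: uniformly labelled tracer); relative_t1_weight models the short-TR
#: saturation bias.
DEFAULT_PEAKS: dict[str, PeakBasis] = {
    "glucose_beta": PeakBasis("glucose_beta", 98.0, 50.0, 1.0),
    "glucose_alpha": PeakBasis("glucose_alpha", 95.0, 50.0, 1.0),
    "lipid": PeakBasis("lipid", 32.0, 80.0, 1.0),
    "lactate": PeakBasis("lactate", 22.8, 40.0, 0.9),
    "alanine": PeakBasis("alanine", 18.9, 40.0, 0.9),
}

#: Resonances seen after a hyperpolarized [1-13C] pyruvate bolus.
PYRUVATE_PEAKS: dict[str, PeakBasis] = {
    "pyruvate": PeakBasis("pyruvate", 172.6, 20.0, 1.0),
    "lactate": PeakBasis("lactate", 184.9, 20.0, 1.0),
    "alanine": PeakBasis("alanine", 178.2, 20.0, 1.0),
    "bicarbonate": PeakBasis("bicarbonate", 162.6, 20.0, 1.0),
    "pyruvate_hydrate": PeakBasis("pyruvate_hydrate", 180.9, 20.0, 1.0),
}

#: Default per-voxel kinetic parameters (tumor tissue).  Rates are per
#: minute; amplitudes arbitrary units.
DEFAULT_REGION_PARAMS: dict[str, float] = {
    "s_total": 100.0,
    "b": 0.9,
    "k_trans": 0.8,
    "k_util": 0.02,
    "lac_max": 30.0,
    "lac_rate": 0.05,
    "ala_max": 10.0,
    "ala_rate": 0.05,
    "lipid": 200.0,
}


# ----------------------------------------------------------------------------
# kinetic forward models
# ----------------------------------------------------------------------------

def glucose_amplitude(
    t_min: np.ndarray | float,
    s_total: float,
    b: float,
    k_trans: float,
    k_util: float,
    t0: float = 5.0,
) -> np.ndarray:
    """Piecewise glucose C1 signal amplitude at time ``t_min`` minutes.

    Transport rise for t < t0, first-order utilization decay for t > 5 t0,
    linear interpolation across the bolus-passage window in between.
    """
    t = np.asarray(t_min, dtype=float)
    rise = s_total * (1.0 - b * np.exp(-k_trans * t))
    decay = s_total * np.exp(-k_util * t)
    v_lo = s_total * (1.0 - b * np.exp(-k_trans * t0))
    v_hi = s_total * np.exp(-k_util * 5.0 * t0)
    frac = np.clip((t - t0) / (4.0 * t0), 0.0, 1.0)
    bridge = v_lo + frac * (v_hi - v_lo)
    out = np.where(t < t0, rise, np.where(t > 5.0 * t0, decay, bridge))
    return out if out.shape else float(out)


def saturating_rise(t_min: np.ndarray | float, a_max: float, rate: float) -> np.ndarray:
    """Monotone appearance model ``a_max (1 - exp(-rate t))`` for lactate/alanine."""
    t = np.asarray(t_min, dtype=float)
    out = a_max * (1.0 - np.exp(-rate * t))
    return out if out.shape else float(out)


def pyruvate_signal(t_s: np.ndarray | float, pyr0: float, k: float, t1: float) -> np.ndarray:
    t = np.asarray(t_s, dtype=float)
    return pyr0 * np.exp(-(k + 1.0 / t1) * t)


def lactate_signal(t_s: np.ndarray | float, pyr0: float, k: float, t1: float) -> np.ndarray:
    t = np.asarray(t_s, dtype=float)
    return pyr0 * (np.exp(-t / t1) - np.exp(-(k + 1.0 / t1) * t))


# ----------------------------------------------------------------------------
# phantom construction
# ----------------------------------------------------------------------------

def make_phantom(
    grid: tuple[int, int],
    region_params,
    noise_sigma: float = 0.0,
    seed: int = 0,
    phase0: float = 0.0,
    phase1: float = 0.0,
    baseline_coeffs: tuple[float, ...] = (),
) -> PhantomTruth:
    """Build a :class:`PhantomTruth` from labelled regions.

    Parameters
    ----------
    grid
        ``(nx, ny)`` voxel counts.
    region_params
        Either a single parameter mapping applied uniformly, or a sequence of
        ``(mask, params)`` pairs where ``mask`` is a boolean array (``None``
        means all voxels) and ``params`` a mapping of kinetic parameters;
        later regions overwrite earlier ones on overlap.  Unspecified
        parameters take :data:`DEFAULT_REGION_PARAMS`.  A region may carry
        ``"tumor": False`` to exclude it from the tumor mask.

    Identical arguments (including ``seed``) reproduce the phantom exactly;
    the seed only reserves noise streams for the simulators.
    """
    nx, ny = int(grid[0]), int(grid[1])
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    if isinstance(region_params, dict):
        regions = [(None, region_params)]
    else:
        regions = list(region_params)

    maps = {k: np.full((nx, ny), v, dtype=float) for k, v in DEFAULT_REGION_PARAMS.items()}
    tumor = np.zeros((nx, ny), dtype=bool)
    for mask, params in regions:
        if mask is None:
            mask = np.ones((nx, ny), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (nx, ny):
            raise ValueError("region mask must match grid")
        if not mask.any():
            raise ValueError("region mask is empty")
        params = dict(params)
        is_tumor = bool(params.pop("tumor", True))
        for key, val in params.items():
            if key not in maps:
                raise ValueError(f"unknown phantom parameter {key!r}")
            if key in PhantomTruth.RATE_KEYS and val < 0:
                raise ValueError(f"rate {key!r} must be non-negative")
            maps[key][mask] = float(val)
        if is_tumor:
            tumor |= mask

    return PhantomTruth(
        grid=(nx, ny),
        maps=maps,
        tumor_mask=tumor,
        noise_sigma=float(noise_sigma),
        phase0=float(phase0),
        phase1=float(phase1),
        baseline_coeffs=tuple(float(c) for c in baseline_coeffs),
        seed=int(seed),
    )


# ----------------------------------------------------------------------------
# spectral forward model
# ----------------------------------------------------------------------------

def lorentzian_fid(
    params: AcquisitionParams,
    peaks: list[PeakBasis],
    amplitudes: np.ndarray,
    n_points: int | None = None,
) -> np.ndarray:
    """Time-domain FID of a sum of Lorentzian resonances.

    ``amplitudes`` is ``(..., n_peaks)``; returns ``(..., n_points)``.  Each
    peak contributes ``A w exp(2 pi i f t) exp(-pi Lambda t)`` with ``f`` the
    offset from the carrier in Hz and ``Lambda`` the FWHM in Hz.
    """
    n = n_points or params.n_points
    t = np.arange(n) * params.dwell_time
    basis = np.empty((len(peaks), n), dtype=complex)
    for i, pk in enumerate(peaks):
        if not params.contains_ppm(pk.center):
            raise ValueError(f"peak {pk.name!r} at {pk.center} ppm is outside the spectral window")
        f_hz = (pk.center - params.reference_ppm) * params.hz_per_ppm
        basis[i] = pk.relative_t1_weight * np.exp((2j * np.pi * f_hz - np.pi * pk.linewidth) * t)
    return np.tensordot(np.asarray(amplitudes, dtype=float), basis, axes=([-1], [0]))


def synthetic_spectrum(fid_frames: np.ndarray) -> np.ndarray:
    """Forward DFT of time-domain frames onto the descending ppm axis."""
    return np.fft.fftshift(np.fft.fft(fid_frames, axis=-1), axes=-1)[..., ::-1]


def _spectrum_to_fid(spec_frames: np.ndarray) -> np.ndarray:
    return np.fft.ifft(np.fft.ifftshift(spec_frames[..., ::-1], axes=-1), axis=-1)


def _phase_twist(ppm: np.ndarray, reference_ppm: float, phase0: float, phase1: float) -> np.ndarray:
    phi = np.deg2rad(phase0 + phase1 * (ppm - reference_ppm))
    return np.exp(-1j * phi)  # simulators *mis-phase*; phasing multiplies by exp(+i phi)


def _baseline_curve(ppm: np.ndarray, reference_ppm: float, sweep_width: float,
                    coeffs: tuple[float, ...]) -> np.ndarray:
    if not coeffs:
        return np.zeros_like(ppm)
    x = (ppm - reference_ppm) / (sweep_width / 2.0)
    return np.polynomial.chebyshev.chebval(x, list(coeffs))


def _metabolite_amplitudes(truth: PhantomTruth, t_min: np.ndarray) -> np.ndarray:
    """Per-voxel, per-peak amplitude curves, shape (nx, ny, n_frames, 5).

    Peak order matches ``list(DEFAULT_PEAKS.values())``: glucose beta/alpha,
    lipid, lactate, alanine.  The alpha anomer tracks the beta curve at the
    equilibrium anomeric ratio (~36:64).
    """
    m = truth.maps
    shape = truth.grid + (t_min.size,)
    amps = np.zeros(shape + (5,), dtype=float)
    # vectorized over voxels (parameters vary per voxel)
    t = t_min[None, None, :]
    s, b = m["s_total"][..., None], m["b"][..., None]
    ktr, ku = m["k_trans"][..., None], m["k_util"][..., None]
    t0 = 5.0
    rise = s * (1.0 - b * np.exp(-ktr * t))
    decay = s * np.exp(-ku * t)
    v_lo = s * (1.0 - b * np.exp(-ktr * t0))
    v_hi = s * np.exp(-ku * 5.0 * t0)
    frac = np.clip((t - t0) / (4.0 * t0), 0.0, 1.0)
    bridge = v_lo + frac * (v_hi - v_lo)
    beta = np.where(t < t0, rise, np.where(t > 5.0 * t0, decay, bridge))
    amps[..., 0] = beta
    amps[..., 1] = (0.36 / 0.64) * beta
    amps[..., 2] = m["lipid"][..., None]
    amps[..., 3] = m["lac_max"][..., None] * (1.0 - np.exp(-m["lac_rate"][..., None] * t))
    amps[..., 4] = m["ala_max"][..., None] * (1.0 - np.exp(-m["ala_rate"][..., None] * t))
    return amps


def _distort_and_noise(
    spec: np.ndarray,
    ppm: np.ndarray,
    params: AcquisitionParams,
    truth: PhantomTruth,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Apply phase error, additive baseline and complex noise in the
    frequency domain.  Noise sd is per spectral bin (real part)."""
    spec = spec * _phase_twist(ppm, params.reference_ppm, truth.phase0, truth.phase1)
    spec = spec + _baseline_curve(ppm, params.reference_ppm, params.sweep_width, truth.baseline_coeffs)
    if truth.noise_sigma > 0 and rng is not None:
        noise = rng.standard_normal(spec.shape) + 1j * rng.standard_normal(spec.shape)
        spec = spec + truth.noise_sigma * noise
    return spec


def simulate_glucose_series(
    truth: PhantomTruth,
    params: AcquisitionParams | None = None,
    duration: float = 3600.0,
    frame_spacing: float = 16.0,
) -> FIDSeries:
    """Non-localized dynamic FID series after a glucose bolus.

    The whole field of view is summed (voxel amplitudes added) and each frame
    rendered as a Lorentzian-sum FID; phase errors, baseline distortion and
    complex Gaussian noise are applied in the frequency domain and
    transformed back, so ``noise_sigma`` is the spectral real-part noise sd.
    """
    params = params or AcquisitionParams()
    if not (duration > frame_spacing > 0):
        raise ValueError("require duration > frame_spacing > 0")
    times = np.arange(frame_spacing, duration + 0.5 * frame_spacing, frame_spacing)
    amps = _metabolite_amplitudes(truth, times / 60.0).sum(axis=(0, 1))  # (n_frames, 5)
    fids = lorentzian_fid(params, list(DEFAULT_PEAKS.values()), amps)
    spec = synthetic_spectrum(fids)
    rng = np.random.default_rng([truth.seed, 1])
    ppm = params.ppm_axis()
    spec = _distort_and_noise(spec, ppm, params, truth, rng)
    return FIDSeries(
        data=_spectrum_to_fid(spec),
        frame_times=times,
        params=params,
        provenance=("simulate_glucose_series",),
    )


def simulate_csi(
    truth: PhantomTruth,
    params: AcquisitionParams | None = None,
    n_frames: int = 75,
    frame_spacing: float = 48.0,
    fov: tuple[float, float] = (2.4, 2.4),
    slab_thickness: float = 1.5,
) -> CSIDataset:
    """Rectilinear phase-encoded CSI series in k-space.

    Each voxel's FID follows its own kinetic parameters; the spatial axes are
    then Fourier transformed (rectilinear phase encoding acquires exactly
    these k-space samples).  Noise is added per k-space point, calibrated so
    the reconstructed image-domain spectra carry real-part noise sd
    ``truth.noise_sigma`` per bin.
    """
    params = params or AcquisitionParams()
    nx, ny = truth.grid
    times = np.arange(1, n_frames + 1) * float(frame_spacing)
    amps = _metabolite_amplitudes(truth, times / 60.0)  # (nx, ny, n_frames, 5)
    fids = lorentzian_fid(params, list(DEFAULT_PEAKS.values()), amps)  # (nx, ny, nf, npts)
    spec = synthetic_spectrum(fids)
    ppm = params.ppm_axis()
    spec = spec * _phase_twist(ppm, params.reference_ppm, truth.phase0, truth.phase1)
    spec = spec + _baseline_curve(ppm, params.reference_ppm, params.sweep_width, truth.baseline_coeffs)
    img = _spectrum_to_fid(spec)  # time-domain voxel FIDs
    img = np.transpose(img, (0, 1, 3, 2))  # (nx, ny, npts, n_frames)
    kspace = np.fft.fft2(img, axes=(0, 1))
    if truth.noise_sigma > 0:
        rng = np.random.default_rng([truth.seed, 2])
        sd_k = truth.noise_sigma * np.sqrt(nx * ny / params.n_points)
        kspace = kspace + sd_k * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )
    return CSIDataset(
        data=kspace,
        fov=fov,
        slab_thickness=slab_thickness,
        frame_times=times,
        params=params,
        domain="k-space",
        spectral_domain="time",
        provenance=("simulate_csi",),
    )


def simulate_pyruvate_series(
    pyr0: float,
    k: float,
    t1: float,
    frame_spacing: float = 1.0,
    n_frames: int = 240,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    k_scaled_form: bool = False,
) -> tuple[KineticTrace, KineticTrace]:
    """Hyperpolarized pyruvate / lactate traces from the two-pool model.

    ``k_scaled_form`` multiplies both pools by the conversion rate ``k``
    (an alternative form of the model found in the literature); the default
    is the mass-balanced solution with Lac(0) = 0.
    """
    if pyr0 <= 0:
        raise ValueError("pyr0 must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    t = np.arange(n_frames) * float(frame_spacing)
    pyr = pyruvate_signal(t, pyr0, k, t1)
    lac = lactate_signal(t, pyr0, k, t1)
    if k_scaled_form:
        pyr, lac = k * pyr, k * lac
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pyr = pyr + noise_sigma * rng.standard_normal(t.shape)
        lac = lac + noise_sigma * rng.standard_normal(t.shape)
    return (
        KineticTrace("pyruvate", t, pyr, time_unit="s"),
        KineticTrace("lactate", t, lac, time_unit="s"),
    )


def tumor_phantom(
    grid: tuple[int, int] = (8, 8),
    noise_sigma: float = 0.0,
    seed: int = 0,
    include_lipid: bool = False,
    include_alanine: bool = False,
    **kwargs,
) -> PhantomTruth:
    """Spatially heterogeneous tumor phantom for imaging experiments.

    A disk-shaped tumor with a smooth radial signal profile, a left-to-right
    gradient of glucose utilization (0.01 to 0.04 per minute) and an
    anti-correlated lactate formation gradient (0.08 down to 0.02 per
    minute), emulating the locally varying glycolysis and fermentation seen
    in necrotic xenografts.  Voxels outside the disk carry no metabolite
    signal.  The lipid and alanine resonances are off by default so that the
    spectrum contains only the glucose and lactate peaks used for mapping;
    pass ``include_lipid``/``include_alanine`` to restore them.
    """
    nx, ny = grid
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) / (min(nx, ny) / 2.0)
    disk = r <= 1.0
    s_total = 100.0 * np.clip(1.2 - 0.8 * r**2, 0.1, None)
    frac = xx / max(nx - 1, 1)
    k_util = 0.01 + 0.03 * frac
    lac_rate = 0.02 + 0.06 * (1.0 - frac)
    regions = []
    for i in range(nx):
        for j in range(ny):
            m = np.zeros(grid, dtype=bool)
            m[i, j] = True
            if disk[i, j]:
                regions.append((m, {
                    "s_total": s_total[i, j],
                    "k_util": k_util[i, j],
                    "lac_rate": lac_rate[i, j],
                    "lac_max": 0.35 * s_total[i, j],
                    "lipid": DEFAULT_REGION_PARAMS["lipid"] if include_lipid else 0.0,
                    "ala_max": DEFAULT_REGION_PARAMS["ala_max"] if include_alanine else 0.0,
                }))
            else:
                regions.append((m, {
                    "s_total": 0.0, "lac_max": 0.0, "lipid": 0.0,
                    "ala_max": 0.0, "tumor": False,
                }))
    return make_phantom(grid, regions, noise_sigma=noise_sigma, seed=seed, **kwargs)
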