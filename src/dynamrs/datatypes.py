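"""Core data containers for dynamic :sup:`13`\\ C MRS and MRSI analysis.

The containers here are deliberately thin: validated dataclasses holding the
complex signal arrays plus the acquisition metadata every downstream stage
needs (ppm axis construction, frame timing, provenance).  All numerical work
lives in the stage modules (:mod:`dynamrs.preprocess`, :mod:`dynamrs.denoise`,
:mod:`dynamrs.kinetics`, :mod:`dynamrs.imaging`).

Conventions
-----------
* ppm axes run *descending* left-to-right (standard NMR display); bin 0 is the
  highest chemical shift.  All window lookups go through :func:`window_indices`.
* FID data are complex, shaped ``(n_frames, n_points)``.
* CSI data are complex, shaped ``(nx, ny, n_points, n_frames)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "AcquisitionParams",
    "PeakBasis",
    "PhantomTruth",
    "FIDSeries",
    "SpectrumSeries",
    "CSIDataset",
    "KineticTrace",
    "PeakWindow",
    "BaselineModel",
    "RankSpec",
    "GlucoseFit",
    "PyruvateFit",
    "RateMap",
    "ppm_axis",
    "window_indices",
    "dose_mmol_per_kg",
    "total_acquisition_time",
]


def ppm_axis(n_points: int, sweep_width: float, reference_ppm: float) -> np.ndarray:
    """Descending ppm axis for an ``n_points`` spectrum.

    The spectral window spans ``sweep_width`` ppm centred on ``reference_ppm``;
    bin 0 carries the highest chemical shift.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    offsets = np.fft.fftshift(np.fft.fftfreq(n_points)) * sweep_width
    return (reference_ppm + offsets)[::-1].copy()


def window_indices(axis: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Boolean index of axis bins within ``center +/- half_width`` ppm."""
    axis = np.asarray(axis, dtype=float)
    sel = np.abs(axis - center) <= half_width
    if not sel.any():
        raise ValueError(
            f"window {center}+/-{half_width} ppm does not intersect the axis "
            f"[{axis.min():.2f}, {axis.max():.2f}]"
        )
    return sel


def dose_mmol_per_kg(volume_ul: float, concentration_mm: float, body_mass_g: float) -> float:
    """Injected dose in mmol per kg body weight.

    ``volume_ul`` microlitres of a ``concentration_mm`` millimolar solution
    into an animal of ``body_mass_g`` grams.
    """
    if volume_ul <= 0 or concentration_mm <= 0 or body_mass_g <= 0:
        raise ValueError("volume, concentration and body mass must be positive")
    mmol = concentration_mm * volume_ul * 1e-6  # mM * L = mmol
    return mmol / (body_mass_g * 1e-3)


def total_acquisition_time(repetition_time: float, n_averages: int, n_scans: int) -> float:
    """Total wall time in seconds of ``n_scans`` stored scans of ``n_averages``
    excitations each at repetition time ``repetition_time`` (s)."""
    if repetition_time <= 0 or n_averages < 1 or n_scans < 1:
        raise ValueError("invalid acquisition timing")
    return repetition_time * n_averages * n_scans


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for a pulse-acquire :sup:`13`\\ C experiment.

    Parameters
    ----------
    n_points
        Number of complex FID samples per stored scan.
    sweep_width
        Spectral width in ppm.
    transmitter_freq
        Carrier frequency in MHz; fixes the Hz-per-ppm scale.
    reference_ppm
        Chemical shift at the centre of the spectral window.
    repetition_time
        TR in seconds.
    flip_angle
        Excitation angle in degrees (Ernst-angle excitation for short TR).
    n_averages
        Excitations averaged per stored scan.
    dead_time_points
        Leading FID points corrupted by receiver dead time.
    """

    n_points: int = 256
    sweep_width: float = 198.6
    transmitter_freq: float = 100.65
    reference_ppm: float = 99.3
    repetition_time: float = 0.050
    flip_angle: float = 12.0
    n_averages: int = 16
    dead_time_points: int = 67

    def __post_init__(self) -> None:
        if not (self.n_points > self.dead_time_points >= 0):
            raise ValueError("require n_points > dead_time_points >= 0")
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be positive")
        if self.transmitter_freq <= 0:
            raise ValueError("transmitter_freq must be positive")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        if not (0 < self.flip_angle <= 90):
            raise ValueError("flip_angle must be in (0, 90] degrees")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")

    @property
    def hz_per_ppm(self) -> float:
        return self.transmitter_freq

    @property
    def sweep_width_hz(self) -> float:
        return self.sweep_width * self.transmitter_freq

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sweep_width_hz

    def ppm_axis(self, n_points: int | None = None) -> np.ndarray:
        return ppm_axis(n_points or self.n_points, self.sweep_width, self.reference_ppm)

    def contains_ppm(self, center: float) -> bool:
        half = self.sweep_width / 2.0
        return abs(center - self.reference_ppm) <= half


@dataclass(frozen=True)
class PeakBasis:
    """A Lorentzian resonance in the simulated basis set.

    ``relative_t1_weight`` is a static amplitude scale in [0, 1] modelling the
    saturation bias of short-TR acquisition (fast-relaxing species appear
    brighter); it skews apparent concentrations but not fitted rates.
    """

    name: str
    center: float
    linewidth: float  # Lorentzian FWHM, Hz
    relative_t1_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive")
        if not (0.0 <= self.relative_t1_weight <= 1.0):
            raise ValueError("relative_t1_weight must lie in [0, 1]")


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("frame_times must be a non-empty 1-D array")
    if not np.all(np.diff(times) > 0):
        raise ValueError("frame_times must be strictly increasing")
    return times


@dataclass
class FIDSeries:
    """Stack of complex FIDs, one per stored frame."""

    data: np.ndarray  # (n_frames, n_points) complex
    frame_times: np.ndarray  # seconds since injection
    params: AcquisitionParams
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("FID data must be 2-D (n_frames, n_points)")
        if not (np.all(np.isfinite(self.data.real)) and np.all(np.isfinite(self.data.imag))):
            raise ValueError("FID data must be finite")
        self.frame_times = _check_times(self.frame_times)
        if self.frame_times.size != self.data.shape[0]:
            raise ValueError("frame_times length must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, note: str, params: AcquisitionParams | None = None) -> "FIDSeries":
        return FIDSeries(
            data=data,
            frame_times=self.frame_times,
            params=params or self.params,
            provenance=self.provenance + (note,),
        )


@dataclass
class SpectrumSeries:
    """Frequency-domain stack with a descending ppm axis.

    ``mode`` records where the series sits in the processing chain:
    ``"complex"`` straight after Fourier transform, ``"phased"`` once
    zero/first-order phase correction has been applied (the real part is then
    the absorption spectrum), or ``"magnitude"`` for modulus spectra.
    """

    data: np.ndarray  # (n_frames, n_freq)
    ppm: np.ndarray  # descending
    frame_times: np.ndarray
    reference_ppm: float
    phase0: float = 0.0  # degrees
    phase1: float = 0.0  # degrees / ppm
    mode: Literal["complex", "phased", "magnitude"] = "complex"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("spectrum data must be 2-D (n_frames, n_freq)")
        if self.ppm.size != self.data.shape[1]:
            raise ValueError("ppm axis length must match n_freq")
        d = np.diff(self.ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        cdata = np.asarray(self.data, dtype=complex)
        if not (np.all(np.isfinite(cdata.real)) and np.all(np.isfinite(cdata.imag))):
            raise ValueError("spectrum data must be finite")
        self.frame_times = _check_times(self.frame_times)
        if self.frame_times.size != self.data.shape[0]:
            raise ValueError("frame_times length must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def real_part(self) -> np.ndarray:
        """Real (absorption-like) view used by baseline and integration."""
        if self.mode == "magnitude":
            return np.abs(self.data)
        return np.real(self.data)

    def window(self, center: float, half_width: float) -> np.ndarray:
        return window_indices(self.ppm, center, half_width)

    def with_data(self, data: np.ndarray, note: str, **changes) -> "SpectrumSeries":
        out = replace(self, data=data, provenance=self.provenance + (note,))
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass
class CSIDataset:
    """Rectilinear phase-encoded chemical-shift-imaging series.

    ``data`` is ``(nx, ny, n_points, n_frames)`` complex; ``domain`` says
    whether the spatial axes are k-space encodes or reconstructed voxels, and
    ``spectral_domain`` whether the third axis holds FID points (``"time"``)
    or spectrum bins on the descending ppm axis (``"frequency"``).
    """

    data: np.ndarray
    fov: tuple[float, float]  # cm
    slab_thickness: float  # cm
    frame_times: np.ndarray  # s
    params: AcquisitionParams
    domain: Literal["k-space", "image"] = "k-space"
    spectral_domain: Literal["time", "frequency"] = "time"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("CSI data must be 4-D (nx, ny, n_points, n_frames)")
        if min(self.data.shape[:2]) < 1:
            raise ValueError("spatial dimensions must be >= 1")
        self.frame_times = _check_times(self.frame_times)
        if self.frame_times.size != self.data.shape[3]:
            raise ValueError("frame_times length must match n_frames")
        if self.slab_thickness <= 0 or min(self.fov) <= 0:
            raise ValueError("geometry must be positive")

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def ppm(self) -> np.ndarray:
        return self.params.ppm_axis(self.data.shape[2])

    def with_data(self, data: np.ndarray, note: str, **changes) -> "CSIDataset":
        out = replace(self, data=data, provenance=self.provenance + (note,))
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass
class KineticTrace:
    """Time course of one integrated peak; input to every kinetic fit."""

    name: str
    times: np.ndarray
    values: np.ndarray
    time_unit: Literal["s", "min"] = "min"
    units: str = "arb"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.values.size:
            raise ValueError("times and values must be 1-D and equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def in_minutes(self) -> "KineticTrace":
        if self.time_unit == "min":
            return self
        return KineticTrace(self.name, self.times / 60.0, self.values, "min", self.units)


@dataclass(frozen=True)
class PeakWindow:
    """Integration window on the ppm axis."""

    name: str
    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


@dataclass
class BaselineModel:
    """Dietrich-style baseline mask plus the fitted Whittaker curve."""

    mask: np.ndarray  # bool per frequency bin, True = baseline point
    smoothed_curve: np.ndarray | None = None  # (n_frames, n_freq)
    smoother_penalty: float = 1e7

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.smoother_penalty < 0:
            raise ValueError("smoother penalty must be >= 0")

    @property
    def baseline_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class RankSpec:
    """Rank choices for low-rank reconstruction.

    Defaults follow the standard protocol: matrix rank 5 for dynamic
    frames x frequency matrices; Tucker ranks 6 in each spatial mode and 8 in
    the spectral and temporal modes of a 4-D CSI tensor.
    """

    matrix_rank: int = 5
    tensor_ranks: tuple[int, int, int, int] = (6, 6, 8, 8)
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.matrix_rank < 1 or any(r < 1 for r in self.tensor_ranks):
            raise ValueError("all ranks must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class PhantomTruth:
    """Per-voxel ground-truth kinetics for the synthetic phantom.

    ``maps`` holds one 2-D float array per parameter: ``s_total``, ``b``,
    ``k_trans`` (1/min), ``k_util`` (1/min), ``lac_max``, ``lac_rate`` (1/min),
    ``ala_max``, ``ala_rate`` (1/min), ``lipid``.
    """

    grid: tuple[int, int]
    maps: dict[str, np.ndarray]
    tumor_mask: np.ndarray
    noise_sigma: float = 0.0
    phase0: float = 0.0
    phase1: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    seed: int = 0

    RATE_KEYS = ("k_trans", "k_util", "lac_rate", "ala_rate")

    def __post_init__(self) -> None:
        nx, ny = self.grid
        if nx < 1 or ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        if self.tumor_mask.shape != (nx, ny):
            raise ValueError("tumor mask must match grid")
        if not self.tumor_mask.any():
            raise ValueError("tumor mask is empty")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for key, arr in self.maps.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (nx, ny):
                raise ValueError(f"map {key!r} must match grid {self.grid}")
            if key in self.RATE_KEYS and (arr < 0).any():
                raise ValueError(f"rates must be non-negative (map {key!r})")
            self.maps[key] = arr


@dataclass
class GlucoseFit:
    """Result of the piecewise glucose kinetic analysis.

    The uptake stage fits ``S(t) = S_total (1 - B exp(-k_trans t))`` on the
    early window; the utilization stage fits a single exponential decay after
    bolus passage, whose rate is the summed first-order loss ``k_util``.
    """

    s_total: float | None = None
    b: float | None = None
    k_trans: float | None = None  # 1/min
    k_util: float | None = None  # 1/min
    t0: float | None = None  # min
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    r_squared: float | None = None
    rss: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.s_total is not None and self.s_total <= 0:
            raise ValueError("s_total must be positive")
        if self.b is not None and not (0.0 <= self.b <= 1.05):
            raise ValueError("B must lie in [0, 1.05]")
        for k in ("k_trans", "k_util"):
            v = getattr(self, k)
            if v is not None and v < -1e-12:
                raise ValueError(f"{k} must be >= 0")


@dataclass
class PyruvateFit:
    """Two-pool unidirectional pyruvate->lactate flux fit.

    ``decay_rate`` is the apparent pyruvate decay ``k + 1/T1``: the sum of the
    net conversion rate and the shared effective relaxation rate.
    """

    pyr0: float
    k: float  # 1/s
    t1: float  # s
    auc_ratios: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    r_squared: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pyr0 <= 0:
            raise ValueError("Pyr0 must be positive")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.t1 <= 0:
            raise ValueError("T1 must be positive")

    @property
    def decay_rate(self) -> float:
        return self.k + 1.0 / self.t1


@dataclass
class RateMap:
    """Voxel-wise metabolic rate map on the (zero-filled) CSI grid."""

    values: np.ndarray  # 1/min
    metabolite: str
    mask: np.ndarray  # True where the fit is valid
    goodness: np.ndarray  # per-voxel r^2 (nan outside mask)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.goodness = np.asarray(self.goodness, dtype=float)
        if not (self.values.shape == self.mask.shape == self.goodness.shape):
            raise ValueError("values, mask and goodness must share a shape")
        if self.mask.any() and not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("rate values must be finite on the valid mask")
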