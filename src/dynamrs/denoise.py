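"""Low-rank noise suppression for dynamic spectroscopy.

Dynamic series are highly redundant: a frames x frequency Casorati matrix of
a few overlapping kinetic processes has rank equal to the number of distinct
temporal behaviours, and a 4-D CSI tensor adds spatial redundancy on top.
Truncating the SVD of the matrix (Eckart-Young best rank-r approximation) or
computing a Tucker approximation of the tensor by higher-order orthogonal
iteration (HOOI) removes the noise components orthogonal to that structure.

Both denoisers are scikit-learn style transformers (``get_params`` /
``set_params`` / ``fit`` / ``transform``) operating on complex arrays;
:func:`svd_denoise` and :func:`hooi_denoise` are thin functional wrappers.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CSIDataset, PeakWindow, SpectrumSeries

__all__ = [
    "SVDDenoiser",
    "TuckerDenoiser",
    "svd_denoise",
    "hooi_denoise",
    "estimate_snr",
]


class SVDDenoiser(TransformerMixin, BaseEstimator):
    """Best rank-``r`` approximation of a dynamic signal matrix.

    ``fit`` computes the SVD of the (frames x frequency, possibly complex)
    matrix and stores the leading ``rank`` right singular vectors;
    ``transform`` projects a matrix onto that row space.  ``fit_transform``
    on the training matrix therefore returns its Eckart-Young optimal
    rank-``r`` approximation (all ``N - r`` trailing singular values zeroed).

    Attributes
    ----------
    components_ : (rank, n_freq) right singular vectors
    singular_values_ : all singular values of the fitted matrix
    """

    def __init__(self, rank: int = 5):
        self.rank = rank

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected a 2-D frames x frequency matrix")
        if not (1 <= self.rank <= min(X.shape)):
            raise ValueError(f"rank must lie in [1, {min(X.shape)}] for shape {X.shape}")
        u, s, vh = np.linalg.svd(X, full_matrices=False)
        self.components_ = vh[: self.rank]
        self.singular_values_ = s
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        vh = self.components_
        return (X @ vh.conj().T) @ vh

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def svd_denoise(matrix: np.ndarray, rank: int = 5) -> np.ndarray:
    """Truncated-SVD reconstruction of ``matrix`` keeping ``rank`` components."""
    return SVDDenoiser(rank=rank).fit_transform(matrix)


# ----------------------------------------------------------------------------
# Tucker / HOOI
# ----------------------------------------------------------------------------

def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def _mode_mult(t: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product ``t x_mode mat`` (mat applied to that axis)."""
    out = np.tensordot(mat, t, axes=(1, mode))
    return np.moveaxis(out, 0, mode)


def _leading_singular_vectors(m: np.ndarray, r: int) -> np.ndarray:
    u, _, _ = np.linalg.svd(m, full_matrices=False)
    return u[:, :r]


class TuckerDenoiser(TransformerMixin, BaseEstimator):
    """Tucker low-multilinear-rank approximation via HOOI.

    Initialization is the HOSVD (leading left singular vectors of each
    unfolding); each sweep then updates one mode's factor from the SVD of the
    tensor projected onto all other factors.  The explained norm is
    monotonically non-decreasing across sweeps; iteration stops when its
    relative change drops below ``tol`` or after ``max_iter`` sweeps.  Ranks
    exceeding a dimension are clipped with a warning.

    Attributes
    ----------
    core_ : compressed core tensor
    factors_ : per-mode orthonormal factor matrices
    fit_history_ : explained norm fraction after each sweep
    n_iter_ : sweeps performed
    """

    def __init__(self, ranks=(6, 6, 8, 8), max_iter: int = 50, tol: float = 1e-6):
        self.ranks = ranks
        self.max_iter = max_iter
        self.tol = tol

    def _effective_ranks(self, shape):
        if len(self.ranks) != len(shape):
            raise ValueError(f"need one rank per mode ({len(shape)}), got {len(self.ranks)}")
        if any(r < 1 for r in self.ranks):
            raise ValueError("all ranks must be >= 1")
        ranks = []
        for r, dim in zip(self.ranks, shape):
            if r > dim:
                warnings.warn(f"rank {r} exceeds dimension {dim}; clipped")
                r = dim
            ranks.append(int(r))
        return ranks

    def fit(self, X, y=None):
        X = np.asarray(X)
        ranks = self._effective_ranks(X.shape)
        nmodes = X.ndim
        norm_x = np.linalg.norm(X)
        factors = [_leading_singular_vectors(_unfold(X, n), ranks[n]) for n in range(nmodes)]
        history: list[float] = []
        prev = -np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            for n in range(nmodes):
                y_t = X
                for m in range(nmodes):
                    if m != n:
                        y_t = _mode_mult(y_t, factors[m].conj().T, m)
                factors[n] = _leading_singular_vectors(_unfold(y_t, n), ranks[n])
            core = X
            for m in range(nmodes):
                core = _mode_mult(core, factors[m].conj().T, m)
            explained = float(np.linalg.norm(core) / norm_x) if norm_x > 0 else 1.0
            history.append(explained)
            if explained > 0 and (explained - prev) < self.tol * explained:
                prev = explained
                break
            prev = explained
        self.core_ = core
        self.factors_ = factors
        self.fit_history_ = history
        self.n_iter_ = it
        self.effective_ranks_ = tuple(ranks)
        return self

    def transform(self, X):
        X = np.asarray(X)
        core = X
        for m, u in enumerate(self.factors_):
            core = _mode_mult(core, u.conj().T, m)
        out = core
        for m, u in enumerate(self.factors_):
            out = _mode_mult(out, u, m)
        return out

    def fit_transform(self, X, y=None):
        self.fit(X)
        out = self.core_
        for m, u in enumerate(self.factors_):
            out = _mode_mult(out, u, m)
        return out


def hooi_denoise(
    csi: CSIDataset,
    ranks: tuple[int, int, int, int] = (6, 6, 8, 8),
    max_iter: int = 50,
    tol: float = 1e-6,
) -> CSIDataset:
    """Tucker/HOOI denoising of an image-domain CSI tensor.

    Ranks are ordered (spatial_x, spatial_y, spectral, temporal); the
    defaults are 6 in each spatial mode and 8 in the spectral and temporal
    modes.
    """
    if csi.domain != "image":
        raise ValueError("hooi_denoise expects an image-domain CSI dataset")
    den = TuckerDenoiser(ranks=ranks, max_iter=max_iter, tol=tol)
    data = den.fit_transform(csi.data)
    return csi.with_data(data, f"hooi_denoise(ranks={tuple(ranks)},n_iter={den.n_iter_})")


# ----------------------------------------------------------------------------
# SNR accounting
# ----------------------------------------------------------------------------

def estimate_snr(
    spec: SpectrumSeries,
    peak_window: PeakWindow,
    noise_window: PeakWindow,
) -> float:
    """Peak SNR: max |signal| in the peak window divided by the sd of the
    real part in a signal-free noise window (pooled over frames)."""
    sel_peak = spec.window(peak_window.center, peak_window.half_width)
    sel_noise = spec.window(noise_window.center, noise_window.half_width)
    if (sel_peak & sel_noise).any():
        raise ValueError("peak and noise windows must be disjoint")
    data = np.asarray(spec.data)
    peak = float(np.max(np.abs(data[:, sel_peak])))
    noise_sd = float(np.std(np.real(data[:, sel_noise])))
    if noise_sd == 0.0:
        raise ValueError("noise window has zero variance; SNR undefined")
    return peak / noise_sd
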