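"""Grubbs-based rejection of nonstationary spectrogram windows.

A short transient (movement artifact, interictal discharge, stimulation
edge) contaminates only a few spectrogram windows but, once averaged, can
dominate the whole PSD estimate.  Two single-pass Grubbs outlier filters
flag such windows:

* the *correlation* filter scores each window by its mean Pearson
  correlation (over a broadband range, default 4-75 Hz, in dB) with every
  other window — windows with a different spectral *shape* stand out;
* the *low-frequency power* filter scores each window by its mean dB power
  over 0-5.3 Hz — transients carry disproportionate low-frequency energy
  and are caught even when their broadband shape stays inconspicuous
  (Pearson correlation is offset-invariant, so a pure power shift escapes
  the first filter).

Scores are z-scored across windows and compared two-sidedly against the
Grubbs critical value

    z_thr = ((N - 1) / sqrt(N)) * sqrt(g / (N - 2 + g)),   g = t^2

with ``t`` the upper critical value of Student's t with ``N - 2`` degrees
of freedom at tail probability ``alpha / (2 N)``, which adapts the cut to
the number of windows.  The background PSD is the linear-power mean of the
surviving windows.  A PCA alternative uses the first principal component
of the mean-centered dB windows as the background estimate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import AllWindowsRejectedError, InvalidArgumentError
from .spectral import Psd, Spectrogram

__all__ = [
    "GrubbsResult",
    "BackgroundPsd",
    "grubbs_threshold",
    "correlation_outliers",
    "lowfreq_power_outliers",
    "background_psd",
    "pca_background",
]

BROADBAND = (4.0, 75.0)
LOWFREQ_BAND = (0.0, 5.3)


@dataclass
class GrubbsResult:
    """Outcome of one Grubbs filter over a spectrogram's windows."""

    statistic_per_window: np.ndarray  # z-scores; NaN for auto-rejected windows
    z_threshold: float
    alpha: float
    n_windows: int
    rejected: np.ndarray  # sorted window indices
    basis: str  # "correlation" | "lowfreq_power"

    def __post_init__(self):
        self.rejected = np.asarray(sorted(self.rejected), dtype=int)

    @property
    def kept(self) -> np.ndarray:
        mask = np.ones(self.n_windows, dtype=bool)
        mask[self.rejected] = False
        return np.nonzero(mask)[0]


@dataclass
class BackgroundPsd:
    """Background spectral estimate with the windows that produced it."""

    psd: Psd
    kept_windows: np.ndarray
    method: str  # "mean_of_kept" | "pca_first_component"

    def __post_init__(self):
        self.kept_windows = np.asarray(self.kept_windows, dtype=int)
        if len(self.kept_windows) == 0:
            raise InvalidArgumentError("kept_windows must be non-empty")


# ---------------------------------------------------------------------------

def grubbs_threshold(N: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical z for ``N`` observations at level ``alpha``."""
    if N < 3:
        raise InvalidArgumentError(f"Grubbs test needs N >= 3 windows, got {N}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * N), N - 2)
    g = t * t
    return float((N - 1) / np.sqrt(N) * np.sqrt(g / (N - 2 + g)))


def _zscore(x: np.ndarray) -> np.ndarray:
    # sample SD (ddof=1): the Grubbs critical value is derived for the
    # maximum deviation studentized by the sample standard deviation
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _grubbs_reject(stat: np.ndarray, valid: np.ndarray, alpha: float,
                   basis: str) -> GrubbsResult:
    """z-score ``stat`` over valid windows and reject beyond the Grubbs cut."""
    n_total = len(valid)
    z = np.full(n_total, np.nan)
    pre_rejected = np.nonzero(~valid)[0]
    idx = np.nonzero(valid)[0]
    N = len(idx)
    if N < 3:
        raise InvalidArgumentError(f"Grubbs test needs >= 3 usable windows, got {N}")
    zv = _zscore(stat[idx])
    z[idx] = zv
    thr = grubbs_threshold(N, alpha)
    if np.std(stat[idx]) == 0:
        rejected = pre_rejected
    else:
        rejected = np.concatenate([pre_rejected, idx[np.abs(zv) > thr]])
    return GrubbsResult(z, thr, alpha, n_total, rejected, basis)


def correlation_outliers(spec: Spectrogram, band=BROADBAND,
                         alpha: float = 0.05) -> GrubbsResult:
    """Reject windows whose broadband dB spectrum decorrelates from the rest.

    Per-window statistic: mean Pearson correlation of the window's dB PSD
    (restricted to ``band``) with every *other* window, passed through the
    Fisher z transform (arctanh) before z-scoring.  Correlations near 1
    are strongly left-skewed, which would inflate the Grubbs test's
    false-alarm rate; arctanh symmetrizes them (it is monotone, so which
    window is most extreme is unchanged).  Windows with zero variance over
    the band cannot enter a correlation and are auto-rejected with a
    warning before the test.
    """
    M = spec.db_matrix()[:, spec.windows[0].band_slice(band)]
    if M.shape[1] < 2:
        raise InvalidArgumentError("band covers fewer than 2 frequency bins")
    n = M.shape[0]
    valid = np.std(M, axis=1) > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} zero-variance window(s) auto-rejected "
            "before the correlation test"
        )
    idx = np.nonzero(valid)[0]
    r = np.corrcoef(M[idx])
    mean_corr_valid = (r.sum(axis=1) - 1.0) / (len(idx) - 1)
    stat = np.zeros(n)
    stat[idx] = np.arctanh(np.clip(mean_corr_valid, -1 + 1e-12, 1 - 1e-12))
    return _grubbs_reject(stat, valid, alpha, "correlation")


def lowfreq_power_outliers(spec: Spectrogram, band=LOWFREQ_BAND,
                           alpha: float = 0.05) -> GrubbsResult:
    """Reject windows with anomalously low or high mean dB power in ``band``."""
    M = spec.db_matrix()[:, spec.windows[0].band_slice(band)]
    if M.shape[1] < 1:
        raise InvalidArgumentError("band covers no frequency bins")
    stat = M.mean(axis=1)
    valid = np.ones(len(stat), dtype=bool)
    return _grubbs_reject(stat, valid, alpha, "lowfreq_power")


def background_psd(spec: Spectrogram, use_correlation: bool = True,
                   use_lowfreq: bool = True, alpha: float = 0.05,
                   band_corr=BROADBAND, band_power=LOWFREQ_BAND) -> BackgroundPsd:
    """Average the windows surviving the combined rejection filters.

    Each enabled filter runs on the *full* window set; the rejection sets
    are unioned.  Survivors are averaged in linear power (the average of
    power estimates is itself a power estimate; averaging in dB would bias
    low) and converted to dB only for display.
    """
    n = spec.n_windows
    rejected = np.zeros(n, dtype=bool)
    if use_correlation:
        rejected[correlation_outliers(spec, band_corr, alpha).rejected] = True
    if use_lowfreq:
        rejected[lowfreq_power_outliers(spec, band_power, alpha).rejected] = True
    kept = np.nonzero(~rejected)[0]
    if len(kept) == 0:
        raise AllWindowsRejectedError(
            "all windows rejected; consider raising alpha or disabling a filter"
        )
    mean_power = spec.power_matrix()[kept].mean(axis=0)
    psd = Psd(spec.frequencies, mean_power, spec.params)
    return BackgroundPsd(psd, kept, "mean_of_kept")


def pca_background(spec: Spectrogram, band=BROADBAND) -> BackgroundPsd:
    """Background estimate from the first principal component of the windows.

    Each window's dB PSD over ``band`` is centered by subtracting its own
    mean; the first principal component across windows then captures the
    spectral shape common to (most of) them.  The component is
    sign-oriented to correlate positively with the mean dB PSD and
    least-squares scaled and shifted onto it, so the result lives on the
    mean spectrum's dB scale.  Bins outside ``band`` are filled from the
    mean dB PSD.
    """
    if spec.n_windows < 2:
        raise InvalidArgumentError("PCA background needs at least 2 windows")
    mask = spec.windows[0].band_slice(band)
    db = spec.db_matrix()
    X = db[:, mask]
    Xc = X - X.mean(axis=1, keepdims=True)  # per-window mean normalization
    # uncentered PCA across windows: every window carries the common
    # background shape coherently, so it dominates the second moment and
    # PC1 recovers it; contamination confined to a minority of windows
    # falls into later components (centering across windows would instead
    # promote exactly those deviations to PC1)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = vt[0]
    mean_db = db.mean(axis=0)
    target = mean_db[mask]
    if np.corrcoef(pc1, target)[0, 1] < 0:
        pc1 = -pc1
    A = np.column_stack([pc1, np.ones_like(pc1)])
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    bg_db = mean_db.copy()
    bg_db[mask] = A @ coef
    psd = Psd(spec.frequencies, 10.0 ** (bg_db / 10.0), spec.params)
    return BackgroundPsd(psd, np.arange(spec.n_windows), "pca_first_component")
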