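"""Power spectra and their periodic/aperiodic decomposition.

Neural power spectra are modelled as an aperiodic power-law background plus
Gaussian oscillatory peaks in log10-power space:

    log10 P(f) = b - chi * log10(f) + sum_k h_k * exp(-(f - c_k)^2 / (2 w_k^2))

``b`` is the aperiodic offset (log10 uV^2/Hz), ``chi`` the aperiodic exponent,
and each peak has a center ``c_k`` (Hz), height ``h_k`` (log10 units) and
standard-deviation width ``w_k`` (Hz).  Band power is the area under the
periodic (peak) component only, which avoids conflating broadband 1/f shifts
with narrowband oscillations.

The module also implements the 1/f-based gait-artifact rule: a walking trial
whose integrated aperiodic power exceeds the resting reference by more than a
configurable fraction (default 50%) is flagged as movement-contaminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "BandDefinition",
    "BANDS",
    "Spectrum",
    "SpectralModel",
    "welch_psd",
    "fit_spectral_model",
    "periodic_band_power",
    "band_power_table",
    "aperiodic_power",
    "flag_gait_artifact",
]


# --------------------------------------------------------------------------
# Band registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidArgumentError(f"band {self.name}: low must be < high")

    def contains(self, f: np.ndarray) -> np.ndarray:
        return (f >= self.low) & (f < self.high)


#: Canonical analysis bands (Hz): low-frequency oscillations, alpha,
#: low/high/all beta, low/high/all gamma.  Adjacent bands are half-open so a
#: grid point is never double counted.
BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("LFO", 2.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("low_beta", 13.0, 20.0),
        BandDefinition("high_beta", 20.0, 35.0),
        BandDefinition("all_beta", 13.0, 35.0),
        BandDefinition("low_gamma", 60.0, 90.0),
        BandDefinition("high_gamma", 90.0, 200.0),
        BandDefinition("all_gamma", 60.0, 200.0),
    )
}

#: Line-noise frequencies whose neighbourhoods (+-3 Hz) are excluded from
#: spectral fitting and from periodic band power.
LINE_HARMONICS = (50.0, 100.0, 150.0)
NOTCH_HALF_WIDTH = 3.0


def _notch_mask(freqs: np.ndarray) -> np.ndarray:
    """Boolean mask of frequencies outside all line-noise exclusion zones."""
    keep = np.ones(freqs.shape, dtype=bool)
    for h in LINE_HARMONICS:
        keep &= np.abs(freqs - h) > NOTCH_HALF_WIDTH
    return keep


# --------------------------------------------------------------------------
# Welch PSD
# --------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray          # Hz
    psd: np.ndarray            # uV^2/Hz
    fs: float
    n_fft: int
    n_overlap: int
    taper: str = "hann"

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(x: np.ndarray, fs: float, n_fft: int = 2000,
              n_overlap: int = 1000) -> Spectrum:
    """Welch PSD estimate (Hann taper, per-segment mean detrend).

    With the defaults and fs = 2000 Hz the frequency resolution is exactly
    1 Hz.  Raises :class:`InsufficientDataError` if the signal is shorter
    than one FFT segment.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("welch_psd expects a 1-D signal")
    if x.size < n_fft:
        raise InsufficientDataError(
            f"signal length {x.size} < n_fft {n_fft}")
    freqs, psd = _sig.welch(x, fs=fs, window="hann", nperseg=n_fft,
                            noverlap=n_overlap, detrend="constant")
    return Spectrum(freqs=freqs, psd=psd, fs=float(fs), n_fft=n_fft,
                    n_overlap=n_overlap)


# --------------------------------------------------------------------------
# Periodic / aperiodic model
# --------------------------------------------------------------------------

@dataclass
class SpectralModel:
    """Aperiodic power law plus Gaussian peaks fitted to a log10 spectrum."""

    offset: float                       # b, log10(uV^2/Hz)
    exponent: float                     # chi, unitless (>= 0 expected)
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    # each peak: (center Hz, height log10-units, width sigma Hz)
    fit_range: tuple[float, float] = (2.0, 200.0)
    r_squared: float = float("nan")
    rmse: float = float("nan")

    def aperiodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def periodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        out = np.zeros(np.shape(freqs), dtype=float)
        for c, h, w in self.peaks:
            out += h * np.exp(-((np.asarray(freqs) - c) ** 2) / (2.0 * w ** 2))
        return out

    def model_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic_log10(freqs) + self.periodic_log10(freqs)


def _gauss_sum(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        c, h, w = params[i:i + 3]
        out += h * np.exp(-((f - c) ** 2) / (2.0 * w ** 2))
    return out


def _gauss_sum_jac(f, *params):
    cols = []
    for i in range(0, len(params), 3):
        c, h, w = params[i:i + 3]
        e = np.exp(-((f - c) ** 2) / (2.0 * w ** 2))
        cols += [h * e * (f - c) / w ** 2,          # d/dc
                 e,                                  # d/dh
                 h * e * (f - c) ** 2 / w ** 3]      # d/dw
    return np.column_stack(cols)


def _robust_aperiodic(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """Linear fit in log-log space, refit on points at/below the median
    residual so oscillatory peaks do not bias the power-law estimate."""
    slope, intercept = np.polyfit(log_f, log_p, 1)
    resid = log_p - (intercept + slope * log_f)
    keep = resid <= np.median(resid)
    if keep.sum() >= 2:
        slope, intercept = np.polyfit(log_f[keep], log_p[keep], 1)
    return intercept, -slope


def fit_spectral_model(spec: Spectrum,
                       fit_range: tuple[float, float] = (2.0, 200.0),
                       max_n_peaks: int = 6,
                       peak_threshold: float = 0.1,
                       peak_width_limits: tuple[float, float] = (1.0, 12.0),
                       ) -> SpectralModel:
    """Decompose a PSD into an aperiodic power law and Gaussian peaks.

    The aperiodic component ``L(f) = b - chi*log10(f)`` is fitted robustly in
    log10-power / log10-frequency coordinates (fit, mask points above the
    median residual, refit).  Peaks are extracted iteratively from the
    flattened spectrum (largest residual first, stopping below
    ``peak_threshold`` log10-units) and then jointly refined; the aperiodic
    component is refit on the peak-removed spectrum.  Frequency bins within
    +-3 Hz of 50/100/150 Hz are excluded throughout.
    """
    lo, hi = fit_range
    in_range = (spec.freqs >= lo) & (spec.freqs <= hi)
    keep = in_range & _notch_mask(spec.freqs)
    f = spec.freqs[keep]
    p = spec.psd[keep]
    if f.size < 8:
        raise InsufficientDataError("too few frequency bins in fit range")
    if np.any(p <= 0):
        raise InvalidArgumentError("PSD must be strictly positive in fit range")

    log_f = np.log10(f)
    log_p = np.log10(p)

    b0, chi0 = _robust_aperiodic(log_f, log_p)
    flat = log_p - (b0 - chi0 * log_f)

    # iterative peak guesses on the flattened spectrum
    wmin, wmax = peak_width_limits
    work = flat.copy()
    guesses: list[tuple[float, float, float]] = []
    for _ in range(max_n_peaks):
        i = int(np.argmax(work))
        h = float(work[i])
        if h < peak_threshold:
            break
        c = float(f[i])
        # half-height width estimate around the maximum
        half = h / 2.0
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < work.size - 1 and work[ri] > half:
            ri += 1
        fwhm = max(f[ri] - f[li], spec.df)
        w = float(np.clip(fwhm / 2.355, wmin, wmax))
        guesses.append((c, h, w))
        work = work - h * np.exp(-((f - c) ** 2) / (2.0 * w ** 2))

    peaks: list[tuple[float, float, float]] = []
    if guesses:
        p0, lb, ub = [], [], []
        for c, h, w in guesses:
            p0 += [c, h, w]
            lb += [lo, 0.0, wmin]
            ub += [hi, np.inf, wmax]
        try:
            popt, _ = curve_fit(_gauss_sum, f, flat, p0=p0,
                                bounds=(lb, ub), jac=_gauss_sum_jac,
                                maxfev=2000, xtol=1e-6)
            peaks = [tuple(popt[i:i + 3]) for i in range(0, len(popt), 3)]
        except RuntimeError:          # keep the iterative guesses
            peaks = guesses
        peaks = [(float(c), float(h), float(w)) for c, h, w in peaks
                 if h >= peak_threshold / 2.0]

    # refit the aperiodic component on the peak-removed spectrum
    peak_log = np.zeros_like(f)
    for c, h, w in peaks:
        peak_log += h * np.exp(-((f - c) ** 2) / (2.0 * w ** 2))
    slope, intercept = np.polyfit(log_f, log_p - peak_log, 1)
    b, chi = float(intercept), float(-slope)

    model = b - chi * log_f + peak_log
    resid = log_p - model
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(np.mean(resid ** 2)))

    return SpectralModel(offset=b, exponent=chi, peaks=sorted(peaks),
                         fit_range=(float(lo), float(hi)),
                         r_squared=r2, rmse=rmse)


# --------------------------------------------------------------------------
# Band power of the periodic component
# --------------------------------------------------------------------------

def _band_grid(band: BandDefinition, df: float = 1.0) -> np.ndarray:
    return np.arange(band.low, band.high, df)


def periodic_band_power(model: SpectralModel, band: BandDefinition | str,
                        df: float = 1.0) -> float:
    """Area under the periodic (peak) component within a band.

    Sum of the fitted Gaussians evaluated on a ``df``-spaced grid over
    [low, high); the half-open convention keeps disjoint bands exactly
    additive.  Peaks centred inside a line-noise exclusion zone are ignored
    with a warning.  Units: log10-power x Hz; always >= 0.
    """
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = model.fit_range
    if band.low < lo or band.high > hi:
        raise InvalidArgumentError(
            f"band {band.name} [{band.low}, {band.high}) outside fit range")
    grid = _band_grid(band, df)
    total = np.zeros_like(grid)
    for c, h, w in model.peaks:
        if not _notch_mask(np.array([c]))[0]:
            warnings.warn(
                f"peak at {c:.1f} Hz lies in a line-noise exclusion zone "
                "and is excluded from band power", stacklevel=2)
            continue
        total += h * np.exp(-((grid - c) ** 2) / (2.0 * w ** 2))
    return float(np.sum(total) * df)


def band_power_table(model: SpectralModel) -> dict[str, float]:
    """Periodic power for every canonical band."""
    return {name: periodic_band_power(model, band)
            for name, band in BANDS.items()}


# --------------------------------------------------------------------------
# 1/f gait-artifact rule
# --------------------------------------------------------------------------

def aperiodic_power(model: SpectralModel, df: float = 1.0) -> float:
    """Integral of the fitted aperiodic model in linear power units over the
    fit range (line-noise exclusion zones omitted)."""
    lo, hi = model.fit_range
    grid = np.arange(lo, hi + df / 2, df)
    grid = grid[_notch_mask(grid)]
    return float(np.sum(10.0 ** model.aperiodic_log10(grid)) * df)


def flag_gait_artifact(walk_model: SpectralModel, rest_model: SpectralModel,
                       threshold: float = 0.5) -> tuple[bool, float]:
    """Movement-artifact rule on the aperiodic (1/f) component.

    Returns ``(flagged, ratio)`` where ``ratio = A_walk / A_rest - 1`` and the
    trial is flagged when the walking aperiodic power exceeds the resting
    reference by more than ``threshold`` (default 50%).
    """
    if walk_model.fit_range != rest_model.fit_range:
        raise InvalidArgumentError("models must share a fit range")
    a_walk = aperiodic_power(walk_model)
    a_rest = aperiodic_power(rest_model)
    ratio = a_walk / a_rest - 1.0
    return bool(ratio > threshold), float(ratio)
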