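"""Time- and frequency-domain heart-rate-variability indices.

Time domain: SDNN, RMSSD, SDSD, pNN50 computed directly from the NN-interval
series.  Frequency domain: VLF/LF/HF band powers, normalized units and the
LF/HF ratio, from a power spectral density of the RR tachogram.

The default spectral estimator is the Lomb–Scargle periodogram evaluated on
the unevenly sampled tachogram (RR series are inherently unevenly sampled in
time); an alternative resamples the tachogram at a fixed rate with cubic
interpolation and applies Welch's averaged periodogram.  Either way the
density is reported in ms²/Hz so that band integration yields power in ms².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .io_formats import RRSeries

__all__ = [
    "TimeDomainIndices",
    "FreqDomainIndices",
    "SpectralConfig",
    "PSDResult",
    "time_domain",
    "tachogram_psd",
    "frequency_domain",
    "extract_features",
    "FEATURE_COLUMNS",
]

#: pNN50 threshold (ms); strict inequality, fixed by the index's name.
PNN_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class TimeDomainIndices:
    """SDNN, RMSSD, SDSD in ms; pNN50 in percent."""

    sdnn: float
    rmssd: float
    sdsd: float
    pnn50: float


@dataclass(frozen=True)
class FreqDomainIndices:
    """Band powers in ms²; normalized units in percent of (LF+HF); LF/HF dimensionless.

    ``lf_nu``, ``hf_nu`` and ``lf_hf`` are NaN when undefined (zero LF+HF or
    zero HF power).
    """

    vlf_power: float
    lf_power: float
    hf_power: float
    lf_nu: float
    hf_nu: float
    lf_hf: float


@dataclass(frozen=True)
class SpectralConfig:
    """Band edges (Hz) and estimator settings for tachogram spectral analysis.

    Band defaults are the standard short-term HRV convention:
    VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz.
    """

    vlf_band: tuple = (0.0033, 0.04)
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.40)
    method: str = "lomb_scargle"
    resample_hz: float = 4.0
    frequency_grid_step: float = 0.001

    def __post_init__(self) -> None:
        bands = [self.vlf_band, self.lf_band, self.hf_band]
        for lo, hi in bands:
            if not (0 <= lo < hi):
                raise ValueError(f"band must satisfy 0 <= lower < upper, got ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi:
                raise ValueError("bands must be non-overlapping and increasing")
        if self.method not in ("lomb_scargle", "resample_welch"):
            raise ValueError(f"unknown spectral method {self.method!r}")
        if self.frequency_grid_step <= 0 or self.resample_hz <= 0:
            raise ValueError("frequency_grid_step and resample_hz must be positive")


@dataclass(frozen=True)
class PSDResult:
    """Power spectral density on a frequency grid, with any estimation warnings."""

    freqs: np.ndarray  # Hz
    density: np.ndarray  # ms^2 / Hz
    warnings: tuple = ()


def time_domain(rr: RRSeries) -> TimeDomainIndices:
    """Compute SDNN, RMSSD, SDSD and pNN50.

    SDNN and SDSD are sample standard deviations (N−1 denominator); RMSSD is
    the root mean square of successive differences; pNN50 is the percentage of
    successive differences with |Δ| strictly greater than 50 ms.
    """
    iv = rr.intervals
    if iv.size < 3:
        raise ValueError("time_domain needs at least 3 intervals")
    diffs = np.diff(iv)
    sdnn = float(np.std(iv, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    sdsd = float(np.std(diffs, ddof=1))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > PNN_THRESHOLD_MS) / diffs.size)
    return TimeDomainIndices(sdnn=sdnn, rmssd=rmssd, sdsd=sdsd, pnn50=pnn50)


def _pseudo_nyquist(rr: RRSeries) -> float:
    # Half the mean beat rate: the natural upper frequency limit of a tachogram.
    return 0.5 / (float(np.mean(rr.intervals)) / 1000.0)


def tachogram_psd(rr: RRSeries, cfg: SpectralConfig = SpectralConfig()) -> PSDResult:
    """Estimate the tachogram PSD over a grid covering (0, max(HF upper, pseudo-Nyquist)].

    The mean is removed before estimation.  Lomb–Scargle output is rescaled so
    the trapezoidal integral of the density over the full grid equals the
    variance of the detrended tachogram, which fixes the units to ms²/Hz.
    A constant series yields identically zero density.
    """
    warns = []
    t = rr.beat_times
    x = rr.intervals - np.mean(rr.intervals)
    duration = t[-1] - t[0]
    lowest_edge = cfg.vlf_band[0]
    if lowest_edge > 0 and duration < 2.0 / lowest_edge:
        warns.append(
            f"duration {duration:.0f}s < {2.0 / lowest_edge:.0f}s recommended for "
            f"the {lowest_edge} Hz band edge; low-frequency powers are unreliable"
        )
    f_max = max(cfg.hf_band[1], _pseudo_nyquist(rr))
    freqs = np.arange(cfg.frequency_grid_step, f_max + cfg.frequency_grid_step / 2, cfg.frequency_grid_step)
    var = float(np.var(x))
    if var == 0.0:
        return PSDResult(freqs=freqs, density=np.zeros_like(freqs), warnings=tuple(warns))

    if cfg.method == "lomb_scargle":
        pgram = signal.lombscargle(t, x, 2.0 * np.pi * freqs)
        total = np.trapezoid(pgram, freqs)
        density = pgram * (var / total) if total > 0 else np.zeros_like(pgram)
    else:  # resample_welch
        fs = cfg.resample_hz
        t_even = np.arange(t[0], t[-1], 1.0 / fs)
        x_even = interpolate.CubicSpline(t, x)(t_even)
        x_even -= x_even.mean()
        nperseg = min(x_even.size, max(256, int(fs * 120)))
        f_w, p_w = signal.welch(x_even, fs=fs, nperseg=nperseg, detrend="constant")
        density = np.interp(freqs, f_w, p_w, left=0.0, right=0.0)
    return PSDResult(freqs=freqs, density=np.maximum(density, 0.0), warnings=tuple(warns))


def _band_power(psd: PSDResult, band: tuple) -> float:
    lo, hi = band
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd.density[mask], psd.freqs[mask]))


def frequency_domain(rr: RRSeries, cfg: SpectralConfig = SpectralConfig()) -> FreqDomainIndices:
    """Band powers by trapezoidal integration of the PSD; normalized units
    lf_nu = 100·LF/(LF+HF), hf_nu = 100·HF/(LF+HF); ratio LF/HF.
    """
    psd = tachogram_psd(rr, cfg)
    vlf = _band_power(psd, cfg.vlf_band)
    lf = _band_power(psd, cfg.lf_band)
    hf = _band_power(psd, cfg.hf_band)
    if lf + hf > 0:
        lf_nu = 100.0 * lf / (lf + hf)
        hf_nu = 100.0 * hf / (lf + hf)
    else:
        lf_nu = hf_nu = float("nan")
    lf_hf = lf / hf if hf > 0 else float("nan")
    return FreqDomainIndices(
        vlf_power=vlf, lf_power=lf, hf_power=hf, lf_nu=lf_nu, hf_nu=hf_nu, lf_hf=lf_hf
    )


#: Column order of the 10-index HRV battery as emitted by :func:`extract_features`.
FEATURE_COLUMNS = (
    "sdnn",
    "rmssd",
    "sdsd",
    "pnn50",
    "vlf_power",
    "lf_power",
    "hf_power",
    "lf_nu",
    "hf_nu",
    "lf_hf",
)


def extract_features(rr: RRSeries, cfg: SpectralConfig = SpectralConfig()) -> dict:
    """The full 10-index battery (4 time-domain + 6 frequency-domain) as a dict."""
    td = time_domain(rr)
    fd = frequency_domain(rr, cfg)
    return {
        "sdnn": td.sdnn,
        "rmssd": td.rmssd,
        "sdsd": td.sdsd,
        "pnn50": td.pnn50,
        "vlf_power": fd.vlf_power,
        "lf_power": fd.lf_power,
        "hf_power": fd.hf_power,
        "lf_nu": fd.lf_nu,
        "hf_nu": fd.hf_nu,
        "lf_hf": fd.lf_hf,
    }
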