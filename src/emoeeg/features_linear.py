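"""The 18 per-band linear features.

For each of alpha, theta and beta (canonical order: alpha 1-6, theta 7-12,
beta 13-18) the block holds: peak, average value, variance, centre
frequency, maximum power and power sum.  Peak is the signed maximum of the
band signal; mean/variance are the plain sample statistics; centre frequency
is the wavelet pseudo-frequency Fa = Fc * fs / a at the scale a whose CWT
response energy is maximal within the band; maximum power and power sum are
the max and sum of the spectrum of the biased autocorrelation estimate
(equivalently the periodogram |X(w)|^2 / N on the full DFT grid, which keeps
the spectrum non-negative and Parseval-exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import BandSignals, band_decompose

#: canonical band order for feature indices 1..18
BAND_ORDER = ("alpha", "theta", "beta")
#: per-band statistic order
STAT_ORDER = ("peak", "mean", "variance", "centre_frequency", "max_power", "power_sum")


class FeatureError(ValueError):
    pass


@dataclass
class LinearFeatureBlock:
    """18 linear features keyed (band, statistic); values() yields them in
    canonical index order 1..18."""

    values_by_key: dict
    flags: dict

    def values(self) -> np.ndarray:
        return np.array(
            [self.values_by_key[(b, s)] for b in BAND_ORDER for s in STAT_ORDER]
        )


def peak(x: np.ndarray) -> float:
    """Signed maximum of the samples."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FeatureError("empty input")
    return float(np.max(x))


def centre_frequency(
    band: np.ndarray,
    fs: float,
    band_range: tuple[float, float],
    wavelet: str = "morl",
    grid_hz: float = 0.25,
) -> float:
    """Dominant pseudo-frequency of a band signal via CWT scale scan.

    Scales a are scanned so the pseudo-frequencies Fa = Fc * fs / a cover the
    band range on a grid_hz grid; the returned Fa maximizes the summed
    squared CWT response.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0 or not np.any(band != 0.0):
        raise FeatureError("zero-energy band signal has no centre frequency")
    lo, hi = band_range
    fc = pywt.central_frequency(wavelet)
    freqs = np.arange(lo, hi + grid_hz / 2.0, grid_hz)
    scales = fc * fs / freqs
    coefs, _ = pywt.cwt(band, scales, wavelet, sampling_period=1.0 / fs)
    energy = np.sum(np.abs(coefs) ** 2, axis=1)
    return float(freqs[int(np.argmax(energy))])


def autocorr_spectrum(x: np.ndarray) -> np.ndarray:
    """Spectrum of the biased autocorrelation estimate, full N-point grid.

    With r(k) the biased autocorrelation, sum_k r(k) e^{-jwk} equals
    |X(w)|^2 / N, so the spectrum is real and non-negative by construction
    and its grid mean equals variance + mean^2 exactly (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise FeatureError("need at least 8 samples for the spectrum")
    X = np.fft.fft(x)
    return (np.abs(X) ** 2) / x.size


def max_power(x: np.ndarray) -> float:
    return float(np.max(autocorr_spectrum(x)))


def power_sum(x: np.ndarray) -> float:
    return float(np.sum(autocorr_spectrum(x)))


def extract_linear(
    epoch: np.ndarray,
    fs: float,
    band_ranges: dict | None = None,
    band_method: str = "butter",
    bands: BandSignals | None = None,
) -> LinearFeatureBlock:
    """All 18 linear features of one single-channel epoch.

    Statistics are computed on the band-filtered signals.  A zero band
    signal is degenerate for centre frequency; it is reported as the band
    midpoint with a flag so batch extraction never aborts.
    """
    if bands is None:
        bands = band_decompose(epoch, fs, band_ranges, method=band_method)
    vals: dict = {}
    flags: dict = {}
    for band, sig in bands.items():
        rng = bands.band_ranges[band]
        vals[(band, "peak")] = peak(sig)
        vals[(band, "mean")] = float(np.mean(sig))
        vals[(band, "variance")] = float(np.var(sig, ddof=1))
        if np.any(sig != 0.0):
            vals[(band, "centre_frequency")] = centre_frequency(sig, fs, rng)
            vals[(band, "max_power")] = max_power(sig)
            vals[(band, "power_sum")] = power_sum(sig)
        else:
            vals[(band, "centre_frequency")] = 0.5 * (rng[0] + rng[1])
            vals[(band, "max_power")] = 0.0
            vals[(band, "power_sum")] = 0.0
            flags[(band, "centre_frequency")] = "degenerate: zero band signal"
    return LinearFeatureBlock(values_by_key=vals, flags=flags)
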