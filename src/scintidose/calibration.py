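"""Am-241 two-peak auto-calibration of the ADC energy scale.

An Am-241 source (e.g. from an ionization smoke detector) shows two features
in the pulse-height histogram: the 59.5 keV gamma line and the envelope of
the Np L X-ray lines between 10 and 23 keV, whose smeared maximum is taken
empirically to sit at 19 keV.  Assuming amplitude is affine in energy, the
two detected peak bins anchor a two-point linear fit

    E(bin) = a * bin + b,   a = (59.5 - 19) / (bin_high - bin_low),

which also delimits the energy range the device can attribute reliably.
The procedure mirrors the device: acquire until the tallest histogram bin
reaches a stop count (default 50) or a timeout passes, smooth with a
centered moving average, locate the two most prominent local maxima, fit,
and persist [a, b] as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .acquisition import PulseHistogram, deadtime_fraction
from .errors import CalibrationFailureError, ConfigError, InsufficientStatisticsError
from .pulse_simulator import DetectorConfig, PulseStream

__all__ = ["Calibration", "acquire_calibration", "smooth_histogram",
           "find_calibration_peaks", "fit_energy_calibration",
           "apply_calibration", "auto_calibrate"]

E_LOW_ANCHOR_KEV = 19.0    # empirical peak of the Am-241 low-energy envelope
E_HIGH_ANCHOR_KEV = 59.5   # Am-241 gamma line
DEFAULT_STOP_COUNT = 50
DEFAULT_TIMEOUT_S = 60.0
DEFAULT_SMOOTH_WINDOW = 7
MIN_PEAK_SEPARATION_BINS = 10
PROMINENCE_FRACTION = 0.10
MIN_USABLE_MAX_COUNT = 10  # required at timeout before peak finding


@dataclass(frozen=True)
class Calibration:
    """Affine ADC->energy map with its validity range.

    a is keV per ADC bin, b the keV offset; valid_range is the energy span
    the device can attribute (bin 0 to the last bin, clipped to the physics
    tables' coverage); created_from stores the detected (low, high) peak
    bins, so applying the map to the high peak returns the 59.5 keV anchor.
    """

    a: float
    b: float
    valid_range: tuple[float, float]
    created_from: tuple[float, float]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("calibration slope must be positive")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("valid_range must be increasing")

    def energy(self, bins):
        """Energy (keV) at ADC bin(s); affine, no range clipping."""
        return self.a * np.asarray(bins, dtype=float) + self.b

    def in_range(self, energies) -> np.ndarray:
        e = np.asarray(energies, dtype=float)
        return (e >= self.valid_range[0]) & (e <= self.valid_range[1])

    def to_json(self, path) -> None:
        payload = {
            "a": self.a,
            "b": self.b,
            "valid_range": list(self.valid_range),
            "peak_bins": list(self.created_from),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["a"], d["b"], tuple(d["valid_range"]), tuple(d["peak_bins"]))


def acquire_calibration(
    stream: PulseStream,
    config: DetectorConfig,
    stop_count: int = DEFAULT_STOP_COUNT,
    timeout_s: float = DEFAULT_TIMEOUT_S,
) -> tuple[PulseHistogram, bool]:
    """Accumulate a histogram event-by-event until the stop rule fires.

    Stops at the first event that lifts any bin to ``stop_count`` (so the
    returned maximum equals ``stop_count`` exactly), or at ``timeout_s``.
    Returns (histogram, timed_out).  Statistics sufficiency is judged by
    the caller (see :func:`auto_calibrate`).
    """
    if stop_count < 1:
        raise ConfigError("stop_count must be >= 1")
    if timeout_s <= 0:
        raise ConfigError("timeout_s must be positive")

    in_time = np.asarray(stream.timestamps) <= timeout_s
    adc = np.asarray(stream.adc_values, dtype=np.int64)[in_time]
    t = np.asarray(stream.timestamps)[in_time]

    # occurrence index of each event within its own bin, in time order
    occ = pd.Series(adc).groupby(adc).cumcount().to_numpy() + 1
    hits = np.nonzero(occ >= stop_count)[0]
    if hits.size:
        stop = int(hits[0])
        counts = np.bincount(adc[: stop + 1], minlength=config.n_bins)
        real_time = float(t[stop])
        timed_out = False
    else:
        counts = np.bincount(adc, minlength=config.n_bins)
        real_time = float(timeout_s)
        timed_out = True
    rate = counts.sum() / real_time if real_time > 0 else 0.0
    hist = PulseHistogram(counts.astype(np.int64), real_time, rate,
                          deadtime_fraction(rate, config.tau))
    return hist, timed_out


def smooth_histogram(counts, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges.

    window must be odd and >= 1; window 1 is the identity. Mass is conserved
    except within window//2 bins of the edges.
    """
    counts = np.asarray(counts, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ConfigError("smoothing window must be odd and >= 1")
    if window > counts.size:
        raise ConfigError("smoothing window larger than histogram")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(counts)))
    n = counts.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _half_max_centroid(counts: np.ndarray, peak: int) -> float:
    """Count-weighted centroid of the contiguous bins >= half the peak height."""
    height = counts[peak]
    lo = peak
    while lo > 0 and counts[lo - 1] >= 0.5 * height:
        lo -= 1
    hi = peak
    while hi < counts.size - 1 and counts[hi + 1] >= 0.5 * height:
        hi += 1
    sel = np.arange(lo, hi + 1)
    w = counts[sel]
    return float(np.sum(sel * w) / np.sum(w))


def find_calibration_peaks(
    smoothed,
    min_separation: int = MIN_PEAK_SEPARATION_BINS,
    prominence_fraction: float = PROMINENCE_FRACTION,
    peak_mode: str = "centroid",
) -> tuple[float, float]:
    """Locate the two major histogram peaks.

    Candidates are local maxima at least ``min_separation`` bins apart with
    prominence >= ``prominence_fraction`` of the global maximum; the two most
    prominent are kept.  Position is either the raw argmax bin
    (``peak_mode='argmax'``) or the centroid of the bins above half maximum
    (default, reduces quantization error).  Raises
    :class:`CalibrationFailureError` with fewer than two qualifying peaks.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if peak_mode not in ("argmax", "centroid"):
        raise ConfigError("peak_mode must be 'argmax' or 'centroid'")
    if smoothed.size < 3 or smoothed.max() <= 0:
        raise CalibrationFailureError("histogram too small or empty for peak search")
    floor = prominence_fraction * smoothed.max()
    peaks, props = find_peaks(smoothed, distance=min_separation, prominence=floor)
    if peaks.size < 2:
        raise CalibrationFailureError(
            f"found {peaks.size} qualifying peak(s); two required — "
            "re-acquire the calibration histogram"
        )
    order = np.argsort(props["prominences"])[::-1][:2]
    chosen = np.sort(peaks[order])
    if peak_mode == "argmax":
        return float(chosen[0]), float(chosen[1])
    return (_half_max_centroid(smoothed, int(chosen[0])),
            _half_max_centroid(smoothed, int(chosen[1])))


def fit_energy_calibration(
    bin_low: float,
    bin_high: float,
    e_low: float = E_LOW_ANCHOR_KEV,
    e_high: float = E_HIGH_ANCHOR_KEV,
    n_bins: int = 1024,
    table_coverage: tuple[float, float] = (10.0, 150.0),
) -> Calibration:
    """Two-point linear fit anchored at the Am-241 peak energies.

    a = (e_high - e_low)/(bin_high - bin_low), b = e_low - a*bin_low; exact
    through both anchors by construction. valid_range spans bin 0 to
    n_bins-1, clipped to the physics-table coverage.
    """
    if not bin_low < bin_high:
        raise CalibrationFailureError("degenerate fit: peak bins must satisfy low < high")
    a = (e_high - e_low) / (bin_high - bin_low)
    b = e_low - a * bin_low
    lo = max(b, table_coverage[0])
    hi = min(a * (n_bins - 1) + b, table_coverage[1])
    return Calibration(a=a, b=b, valid_range=(lo, hi),
                       created_from=(float(bin_low), float(bin_high)))


def apply_calibration(bins, calibration: Calibration):
    """Map ADC bins to energies; returns (energies_keV, in_valid_range mask)."""
    e = calibration.energy(bins)
    return e, calibration.in_range(e)


def auto_calibrate(
    stream: PulseStream,
    config: DetectorConfig,
    stop_count: int = DEFAULT_STOP_COUNT,
    timeout_s: float = DEFAULT_TIMEOUT_S,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    peak_mode: str = "centroid",
    table_coverage: tuple[float, float] = (10.0, 150.0),
) -> tuple[Calibration, PulseHistogram]:
    """Full device calibration: acquire, smooth, find peaks, fit.

    Raises :class:`InsufficientStatisticsError` if acquisition timed out with
    a maximum bin count below the usable floor.
    """
    hist, timed_out = acquire_calibration(stream, config, stop_count, timeout_s)
    if timed_out and hist.counts.max() < MIN_USABLE_MAX_COUNT:
        raise InsufficientStatisticsError(
            f"calibration timed out with max bin count {int(hist.counts.max())} "
            f"< {MIN_USABLE_MAX_COUNT}; bring the source closer and retry"
        )
    smoothed = smooth_histogram(hist.counts, smooth_window)
    bin_low, bin_high = find_calibration_peaks(smoothed, peak_mode=peak_mode)
    cal = fit_energy_calibration(bin_low, bin_high, n_bins=config.n_bins,
                                 table_coverage=table_coverage)
    return cal, hist
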