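"""Pulse-height histograms and non-paralyzable deadtime arithmetic.

The digitizer is busy for a fixed time tau after every accepted pulse, so a
true trigger rate ``n`` yields the observed rate ``n / (1 + n*tau)``: linear
at low rates, saturating at 1/tau.  The device estimates its deadtime
fraction as ``observed_rate * tau`` and, inside a guarded reliable region,
inverts the loss by scaling counts with ``1 / (1 - deadtime_fraction)`` —
exact algebra for the non-paralyzable model, applied uniformly per bin
(deadtime is energy-independent here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SaturationError, UnreliableRateError
from .pulse_simulator import DetectorConfig, PulseStream

__all__ = ["PulseHistogram", "build_histogram", "observed_rate",
           "deadtime_fraction", "correct_counts", "DEADTIME_CORRECTION_CAP"]

# Beyond this deadtime fraction the output rate is declared unreliable and
# the correction (factor > 10x) is refused.
DEADTIME_CORRECTION_CAP = 0.9


@dataclass
class PulseHistogram:
    """Counts per ADC bin plus acquisition metadata.

    Invariants: sum(counts) == observed_rate * real_time (to rounding);
    deadtime_fraction == observed_rate * tau.
    """

    counts: np.ndarray
    real_time: float
    observed_rate: float
    deadtime_fraction: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if not 0 <= self.deadtime_fraction < 1:
            raise ValueError("deadtime fraction must lie in [0, 1)")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# real_time_s={self.real_time!r}\n")
            fh.write(f"# observed_rate_cps={self.observed_rate!r}\n")
            fh.write(f"# deadtime_fraction={self.deadtime_fraction!r}\n")
            fh.write("bin,counts\n")
            for b, c in enumerate(self.counts):
                fh.write(f"{b},{c}\n")

    @classmethod
    def from_csv(cls, path) -> "PulseHistogram":
        meta = {}
        bins, counts = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = float(val)
                    continue
                if not line or line.startswith("bin,"):
                    continue
                b, c = line.split(",")
                bins.append(int(b))
                counts.append(float(c))
        arr = np.zeros(max(bins) + 1 if bins else 0)
        arr[np.array(bins, dtype=int)] = counts
        return cls(arr, meta.get("real_time_s", 0.0),
                   meta.get("observed_rate_cps", 0.0),
                   meta.get("deadtime_fraction", 0.0))


def build_histogram(stream: PulseStream, config: DetectorConfig) -> PulseHistogram:
    """Histogram a pulse stream into ``config.n_bins`` ADC bins.

    An empty stream yields a valid all-zero histogram. Counts conserve the
    stream length; the metadata (observed rate, deadtime fraction) is
    derived from the stream duration and the configured tau.
    """
    if stream.duration <= 0:
        raise ValueError("stream duration must be positive")
    adc = np.asarray(stream.adc_values, dtype=np.int64)
    if adc.size and (adc.min() < 0 or adc.max() >= config.n_bins):
        raise ValueError("adc values outside [0, n_bins)")
    counts = np.bincount(adc, minlength=config.n_bins).astype(np.int64)
    rate = adc.size / stream.duration
    return PulseHistogram(
        counts=counts,
        real_time=stream.duration,
        observed_rate=rate,
        deadtime_fraction=deadtime_fraction(rate, config.tau),
    )


def observed_rate(true_rate: float, tau: float) -> float:
    """Output rate of a non-paralyzable counter: n / (1 + n*tau).

    Strictly increasing and concave in ``true_rate``, with asymptote 1/tau.
    """
    if true_rate < 0 or tau <= 0:
        raise ValueError("need true_rate >= 0 and tau > 0")
    return true_rate / (1.0 + true_rate * tau)


def deadtime_fraction(observed: float, tau: float) -> float:
    """Deadtime fraction estimated on-device: observed rate times tau."""
    if observed < 0 or tau <= 0:
        raise ValueError("need observed >= 0 and tau > 0")
    frac = observed * tau
    if frac >= 1.0:
        raise SaturationError(
            f"observed rate {observed:g} with tau {tau:g} implies deadtime "
            f"fraction {frac:g} >= 1; such a rate is not physically observable"
        )
    return frac


def correct_counts(histogram: PulseHistogram, tau: float | None = None,
                   cap: float = DEADTIME_CORRECTION_CAP) -> np.ndarray:
    """Deadtime-corrected (real-valued) counts per bin.

    Scales every bin by 1/(1 - deadtime_fraction), which inverts
    ``observed_rate`` exactly: m -> m/(1+m*tau) -> m.  Refuses fractions at
    or beyond ``cap``, where the device output is unreliable.
    """
    frac = (histogram.deadtime_fraction if tau is None
            else deadtime_fraction(histogram.observed_rate, tau))
    if frac >= cap:
        raise UnreliableRateError(
            f"deadtime fraction {frac:.3f} >= guard cap {cap:g}; "
            "output rate unreliable, correction refused"
        )
    return histogram.counts / (1.0 - frac)
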