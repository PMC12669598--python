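"""Software emulation of the wearable device loop.

A single button drives a four-screen state machine: short presses toggle
the dose-rate and accumulated-dose displays, a long press opens the options
menu, where a short press resets the dose values (calibration survives —
it persists like flash memory) and a long press starts the calibration
procedure.  A 1 Hz tick acquires one window, updates the dose state, and
appends to a bounded ring-buffer log holding the most recent 10 hours
(36,000 samples) for export.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .acquisition import build_histogram
from .calibration import Calibration, auto_calibrate
from .dose_engine import DoseState, accumulate, spectrum_dose
from .physics_tables import AttenuationTable, DoseCoefficientTable
from .pulse_simulator import DetectorConfig, SourceModel, detect_and_digitize

__all__ = ["Screen", "Event", "DeviceState", "DoseLog", "LogSample",
           "step_state", "log_sample", "export_log", "read_log", "run_session"]

DEFAULT_RETENTION_HOURS = 10.0
LOG_HEADER = ["t_s", "dose_rate_uSv_h", "accumulated_uSv",
              "deadtime_fraction", "discarded_counts"]


class Screen(str, Enum):
    DOSE_RATE = "dose_rate"
    ACCUMULATED = "accumulated"
    OPTIONS = "options"
    CALIBRATING = "calibrating"


class Event(str, Enum):
    SHORT_PRESS = "short_press"
    LONG_PRESS = "long_press"
    TICK = "tick"


@dataclass(frozen=True)
class LogSample:
    t_s: float
    dose_rate_uSv_h: float
    accumulated_uSv: float
    deadtime_fraction: float = 0.0
    discarded_counts: float = 0.0


class DoseLog:
    """Ring buffer of 1 Hz dose samples; oldest entry evicted at capacity."""

    def __init__(self, retention_hours: float = DEFAULT_RETENTION_HOURS,
                 rate_hz: float = 1.0):
        if retention_hours <= 0 or rate_hz <= 0:
            raise ValueError("retention and rate must be positive")
        self.capacity = int(round(retention_hours * 3600 * rate_hz))
        self._buf: deque[LogSample] = deque(maxlen=self.capacity)

    def __len__(self) -> int:
        return len(self._buf)

    def __iter__(self):
        return iter(self._buf)

    @property
    def samples(self) -> list[LogSample]:
        return list(self._buf)

    def append(self, sample: LogSample) -> None:
        if self._buf and sample.t_s <= self._buf[-1].t_s:
            raise ValueError(
                f"log timestamps must strictly increase "
                f"({sample.t_s} after {self._buf[-1].t_s})"
            )
        self._buf.append(sample)

    def span_seconds(self) -> float:
        """Time covered by a full buffer at the nominal rate."""
        return float(len(self._buf)) if self._buf else 0.0


def log_sample(log: DoseLog, sample: LogSample) -> DoseLog:
    """Append one sample, evicting the single oldest entry when full."""
    log.append(sample)
    return log


def export_log(log: DoseLog, path) -> None:
    """Write the log as CSV; round-trips bit-exactly through read_log."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_HEADER)
        for s in log:
            writer.writerow([repr(s.t_s), repr(s.dose_rate_uSv_h),
                             repr(s.accumulated_uSv), repr(s.deadtime_fraction),
                             repr(s.discarded_counts)])


def read_log(path, retention_hours: float = DEFAULT_RETENTION_HOURS) -> DoseLog:
    log = DoseLog(retention_hours)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != LOG_HEADER:
            raise ValueError(f"unexpected log header {header!r}")
        for row in reader:
            log.append(LogSample(*(float(x) for x in row)))
    return log


@dataclass
class DeviceState:
    """Screen, dose tally, calibration, and log — the whole device."""

    screen: Screen = Screen.DOSE_RATE
    dose: DoseState = field(default_factory=DoseState)
    calibration: Optional[Calibration] = None
    log: DoseLog = field(default_factory=DoseLog)
    clock_s: float = 0.0


def step_state(state: DeviceState, event: Event) -> DeviceState:
    """Advance the single-button state machine (mutates and returns state).

    Transitions: dose_rate <-> accumulated on short press; long press from
    either display opens options; in options a short press resets the dose
    values and returns to the dose-rate display, a long press starts
    calibration; the calibrating screen ignores presses and returns to the
    dose-rate display on the tick that completes it.  A tick on a display
    screen advances the 1 Hz clock.  Every event is legal on every screen;
    undefined combinations are no-ops.
    """
    event = Event(event)
    s = state.screen
    if event is Event.SHORT_PRESS:
        if s is Screen.DOSE_RATE:
            state.screen = Screen.ACCUMULATED
        elif s is Screen.ACCUMULATED:
            state.screen = Screen.DOSE_RATE
        elif s is Screen.OPTIONS:
            state.dose.reset()
            state.screen = Screen.DOSE_RATE
    elif event is Event.LONG_PRESS:
        if s in (Screen.DOSE_RATE, Screen.ACCUMULATED):
            state.screen = Screen.OPTIONS
        elif s is Screen.OPTIONS:
            state.screen = Screen.CALIBRATING
    elif event is Event.TICK:
        state.clock_s += 1.0
        if s is Screen.CALIBRATING:
            state.screen = Screen.DOSE_RATE
    return state


def run_session(
    source: SourceModel,
    config: DetectorConfig,
    attenuation: AttenuationTable,
    dose_table: DoseCoefficientTable,
    duration_s: int,
    seed,
    calibration: Optional[Calibration] = None,
    calibration_source: Optional[SourceModel] = None,
    retention_hours: float = DEFAULT_RETENTION_HOURS,
) -> tuple[DoseLog, DoseState]:
    """Emulate ``duration_s`` seconds of 1 Hz operation against a source.

    If no calibration is supplied, one is produced first from
    ``calibration_source`` (default: a bright Am-241 source), mirroring the
    on-device procedure.
    """
    geometry = config.geometry
    rng = np.random.SeedSequence(seed)
    cal_seed, *win_seeds = rng.spawn(duration_s + 1)
    if calibration is None:
        cal_src = calibration_source or SourceModel(kind="am241", intensity=2000.0)
        cs = np.random.default_rng(cal_seed)
        energies = cal_src.sample(200_000, cs)
        stream = detect_and_digitize(energies, cal_src.intensity, config,
                                     duration=100.0, seed=cs,
                                     attenuation=attenuation)
        calibration, _ = auto_calibrate(stream, config)

    log = DoseLog(retention_hours)
    state = DoseState(window=1.0)
    for k, ws in enumerate(win_seeds):
        wrng = np.random.default_rng(ws)
        energies = source.sample(max(int(source.intensity * 2) + 100, 100), wrng)
        stream = detect_and_digitize(energies, source.intensity, config,
                                     duration=1.0, seed=wrng,
                                     attenuation=attenuation)
        hist = build_histogram(stream, config)
        inc = spectrum_dose(hist, calibration, attenuation, dose_table, geometry)
        accumulate(state, inc.dose_sv)
        log.append(LogSample(
            t_s=float(k + 1),
            dose_rate_uSv_h=state.last_rate * 1e6,
            accumulated_uSv=state.accumulated_dose * 1e6,
            deadtime_fraction=hist.deadtime_fraction,
            discarded_counts=inc.discarded_counts,
        ))
    return log, state
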