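"""Calibrated pulse-height spectrum -> effective dose.

Per acquisition window the dose increment is

    dD = sum_bins  counts_corr(bin) / eta(E_bin) * e(E_bin) / A,

where counts are first deadtime-corrected, division by the absorption
efficiency eta converts detected to incident photons, and e(E)/A (pSv per
incident photon, ICRP 116 AP coefficients over the crystal face area) maps
photons to effective dose.  Energies are evaluated at bin centers through
the linear calibration.  Bins whose energy falls outside the calibration's
valid range or the tables' coverage, or where eta is below a small floor
(dividing would explosively amplify noise counts), are excluded and
reported in a discard counter rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import DEADTIME_CORRECTION_CAP, PulseHistogram, correct_counts
from .calibration import Calibration
from .errors import DeviceStateError
from .physics_tables import (AttenuationTable, DetectorGeometry,
                             DoseCoefficientTable)

__all__ = ["DoseState", "DoseIncrement", "spectrum_dose", "dose_rate", "accumulate"]

EFFICIENCY_FLOOR = 0.01
PSV_TO_SV = 1e-12


@dataclass(frozen=True)
class DoseIncrement:
    """One window's dose increment plus discard accounting."""

    dose_sv: float
    counts_used: float
    discarded_counts: float


@dataclass
class DoseState:
    """Running dose tally: accumulated dose (Sv), last dose rate (Sv/h).

    accumulated_dose never decreases except through :meth:`reset`.
    """

    accumulated_dose: float = 0.0
    last_rate: float = 0.0
    window: float = 1.0  # seconds per update

    def reset(self) -> None:
        self.accumulated_dose = 0.0
        self.last_rate = 0.0


def spectrum_dose(
    histogram: PulseHistogram,
    calibration: Calibration,
    attenuation: AttenuationTable,
    dose_table: DoseCoefficientTable,
    geometry: DetectorGeometry,
    efficiency_floor: float = EFFICIENCY_FLOOR,
    deadtime_cap: float = DEADTIME_CORRECTION_CAP,
) -> DoseIncrement:
    """Effective-dose increment (Sv) for one histogram window.

    Deadtime correction is applied before the efficiency correction; both
    are multiplicative per bin so the order is fixed only for
    reproducibility.  Raises DeviceStateError without a calibration and
    UnreliableRateError (via correct_counts) beyond the deadtime guard cap.
    """
    if calibration is None:
        raise DeviceStateError("device must be calibrated first")
    corrected = correct_counts(histogram, cap=deadtime_cap)
    occupied = np.nonzero(corrected > 0)[0]
    if occupied.size == 0:
        return DoseIncrement(0.0, 0.0, 0.0)

    energies = calibration.energy(occupied)
    usable = (calibration.in_range(energies)
              & attenuation.in_range(energies)
              & dose_table.in_range(energies))
    idx = occupied[usable]
    e_keV = energies[usable]
    discarded = float(corrected[occupied[~usable]].sum())
    if idx.size == 0:
        return DoseIncrement(0.0, 0.0, discarded)

    eta = 1.0 - np.exp(-attenuation(e_keV) * geometry.thickness_mm)
    deep = eta >= efficiency_floor
    discarded += float(corrected[idx[~deep]].sum())
    idx, e_keV, eta = idx[deep], e_keV[deep], eta[deep]
    if idx.size == 0:
        return DoseIncrement(0.0, 0.0, discarded)

    per_photon_psv = dose_table(e_keV) / geometry.area_cm2
    dose_psv = float(np.sum(corrected[idx] / eta * per_photon_psv))
    return DoseIncrement(dose_psv * PSV_TO_SV, float(corrected[idx].sum()), discarded)


def dose_rate(increment_sv: float, window_s: float) -> float:
    """Dose rate in Sv/h from a window increment: increment/window * 3600."""
    if window_s <= 0:
        raise ValueError("window must be positive")
    return increment_sv / window_s * 3600.0


def accumulate(state: DoseState, increment_sv: float) -> DoseState:
    """Add one window's increment to the running tally (in place; returns state)."""
    if increment_sv < 0:
        raise ValueError("dose increment must be non-negative")
    state.accumulated_dose += increment_sv
    state.last_rate = dose_rate(increment_sv, state.window)
    return state
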