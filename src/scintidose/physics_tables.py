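"""Tabulated photon physics: crystal attenuation and fluence-to-dose coefficients.

Two energy-indexed tables drive the dose algorithm:

* the linear attenuation coefficient :math:`\\mu(E)` of the LYSO crystal,
  from which the slab absorption efficiency
  :math:`\\eta(E) = 1 - e^{-\\mu(E)\\,t}` follows for thickness ``t``; and
* the ICRP 116 effective-dose-per-fluence coefficients :math:`e(E)`
  (pSv·cm², anteroposterior geometry), which scaled by the crystal face
  area ``A`` give the effective dose contributed by a single photon
  incident on the detector.

Both quantities are near power-law in energy, so interpolation between grid
points is linear in log-log space — the standard choice for photon cross
sections.  The packaged attenuation grid contains points immediately below
and above the Lu K-edge (63.3 keV) so no interpolated segment bridges the
discontinuity.  Energies outside a table's grid raise
:class:`~scintidose.errors.EnergyRangeError` rather than extrapolating: the
device only attributes energies inside its calibrated spectral range.

Units package-wide: keV, mm, cm² (mm² inputs converted internally), pSv for
per-photon dose, Sv for reported doses, seconds for time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import EnergyRangeError, TableFormatError

__all__ = [
    "AttenuationTable",
    "DoseCoefficientTable",
    "DetectorGeometry",
    "absorption_efficiency",
    "per_photon_dose",
    "load_tables",
    "load_default_tables",
    "load_filter_table",
]

_DATA_PKG = "scintidose.data"
DEFAULT_ATTENUATION_RESOURCE = "lyso_attenuation.csv"
DEFAULT_COEFFICIENT_RESOURCE = "icrp116_ap_dose_coefficients.csv"


def _loglog_interp(energy: np.ndarray, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(energy), np.log(grid), np.log(values)))


@dataclass(frozen=True)
class _EnergyTable:
    """Ascending energy grid (keV) with strictly positive values."""

    energies: np.ndarray
    values: np.ndarray
    name: str = "table"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if e.ndim != 1 or e.shape != v.shape or e.size < 2:
            raise TableFormatError(f"{self.name}: need matching 1-d grids of length >= 2")
        if not np.all(np.diff(e) > 0):
            raise TableFormatError(f"{self.name}: energy grid must be strictly increasing")
        if not np.all(v > 0):
            raise TableFormatError(f"{self.name}: all values must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "values", v)

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    def _check_range(self, energy: np.ndarray) -> None:
        energy = np.asarray(energy, dtype=float)
        if np.any(energy < self.e_min) or np.any(energy > self.e_max):
            raise EnergyRangeError(
                f"{self.name}: energy outside tabulated grid "
                f"[{self.e_min:g}, {self.e_max:g}] keV"
            )

    def __call__(self, energy):
        """Log-log interpolated value(s) at ``energy`` (keV)."""
        self._check_range(energy)
        scalar = np.isscalar(energy)
        out = _loglog_interp(np.atleast_1d(np.asarray(energy, dtype=float)),
                             self.energies, self.values)
        return float(out[0]) if scalar else out

    def in_range(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        return (e >= self.e_min) & (e <= self.e_max)


@dataclass(frozen=True)
class AttenuationTable(_EnergyTable):
    """Linear attenuation coefficient of the scintillator, 1/mm vs keV."""

    name: str = "attenuation table"


@dataclass(frozen=True)
class DoseCoefficientTable(_EnergyTable):
    """Effective dose per fluence e(E), pSv·cm² (AP geometry), vs keV."""

    name: str = "dose-coefficient table"


@dataclass(frozen=True)
class DetectorGeometry:
    """Slab crystal geometry: face area in mm², thickness in mm.

    Zero thickness is allowed as the degenerate no-absorber limit.
    """

    area_mm2: float = 25.0
    thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("detector area must be positive")
        if self.thickness_mm < 0:
            raise ValueError("crystal thickness must be non-negative")

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / 100.0


def absorption_efficiency(energy, geometry: DetectorGeometry, table: AttenuationTable):
    """Probability that a photon of ``energy`` (keV) interacts in the crystal.

    eta(E) = 1 - exp(-mu(E) * t) with mu interpolated log-log on the table
    grid. Raises :class:`EnergyRangeError` outside the grid.
    """
    mu = table(energy)
    return 1.0 - np.exp(-np.asarray(mu) * geometry.thickness_mm) if not np.isscalar(mu) \
        else 1.0 - float(np.exp(-mu * geometry.thickness_mm))


def per_photon_dose(energy, geometry: DetectorGeometry, table: DoseCoefficientTable):
    """Effective dose (pSv) per photon incident on the crystal face.

    A fluence of one photon over the face area A (cm²) is 1/A cm⁻², so the
    per-photon dose is e(E)/A. Halving the area doubles the per-photon dose.
    """
    e = table(energy)
    return e / geometry.area_cm2


def _parse_table_csv(path, value_column: str, cls, name: str):
    energies: list[float] = []
    values: list[float] = []
    seen: set[float] = set()
    with open(path) as fh:
        rows = list(fh)
    header_seen = False
    for lineno, raw in enumerate(rows, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[0] != "energy_keV" or len(cols) != 2:
                raise TableFormatError(
                    f"{path}, row {lineno}: expected header 'energy_keV,{value_column}'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TableFormatError(f"{path}, row {lineno}: expected two columns")
        try:
            e, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise TableFormatError(f"{path}, row {lineno}: non-numeric value") from exc
        if e in seen:
            raise TableFormatError(f"{path}, row {lineno}: duplicate energy {e:g} keV")
        if energies and e < energies[-1]:
            raise TableFormatError(f"{path}, row {lineno}: energies must ascend")
        if v <= 0:
            raise TableFormatError(f"{path}, row {lineno}: non-positive value {v:g}")
        seen.add(e)
        energies.append(e)
        values.append(v)
    if len(energies) < 2:
        raise TableFormatError(f"{path}: fewer than two data rows")
    return cls(np.array(energies), np.array(values), name=name)


def load_tables(attenuation_path, coefficient_path):
    """Load and validate the two physics CSVs.

    Format: '#'-prefixed comment lines, a ``energy_keV,<value>`` header, then
    numeric rows with strictly ascending energies and positive values.
    """
    att = _parse_table_csv(attenuation_path, "mu_per_mm", AttenuationTable,
                           "attenuation table")
    dose = _parse_table_csv(coefficient_path, "pSv_cm2", DoseCoefficientTable,
                            "dose-coefficient table")
    return att, dose


def _resource_path(resource: str):
    return resources.files(_DATA_PKG).joinpath(resource)


def load_default_tables():
    """Packaged LYSO attenuation + ICRP 116 AP dose-coefficient tables."""
    with resources.as_file(_resource_path(DEFAULT_ATTENUATION_RESOURCE)) as p_att, \
            resources.as_file(_resource_path(DEFAULT_COEFFICIENT_RESOURCE)) as p_dose:
        return load_tables(p_att, p_dose)


def load_filter_table(material: str) -> AttenuationTable:
    """Packaged attenuation table for a beam-filtration material (pb or al)."""
    material = material.lower()
    if material not in ("pb", "al"):
        raise ValueError(f"no packaged filter table for {material!r}")
    with resources.as_file(_resource_path(f"{material}_attenuation.csv")) as p:
        return _parse_table_csv(p, "mu_per_mm", AttenuationTable,
                                f"{material} filter table")
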