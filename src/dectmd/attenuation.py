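"""Energy-dependent mass attenuation coefficients for basis materials.

This module holds the material library used by two-material decomposition:
per-material mass attenuation curves (cm^2/g versus photon energy in keV),
interpolation between tabulated energies, conversions between linear
attenuation and CT numbers (Hounsfield units), and a simple parametric
attenuation model (photoelectric + Klein-Nishina Compton) used to fabricate
plausible fixture curves when no measured table is available.

Units are fixed throughout: keV, cm^2/g, g/cm^3, 1/cm, HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MaterialSpec",
    "AttenuationTable",
    "EnergyPair",
    "AttenuationFormatError",
    "ExtrapolationError",
    "load_attenuation_table",
    "mass_attenuation",
    "hu_from_mu",
    "mu_from_hu",
    "parametric_attenuation",
    "klein_nishina_cross_section",
]

#: Classical electron radius in cm.
_R_E = 2.8179403262e-13
#: Electron rest energy in keV.
_MEC2_KEV = 510.99895
#: Avogadro's number, 1/mol.
_N_AVOGADRO = 6.02214076e23
#: Photoelectric scale, calibrated so a water-like material (Z_eff = 7.42,
#: density 1 g/cm^3) evaluates to ~0.268 1/cm at 40 keV.
_C_PE = 8.884177
#: Working energy range of the model, keV.
WORKING_RANGE = (40.0, 150.0)


class AttenuationFormatError(ValueError):
    """Raised when an attenuation CSV violates the expected dialect."""


class ExtrapolationError(ValueError):
    """Raised when a query energy falls outside a material's tabulated span."""


@dataclass(frozen=True)
class MaterialSpec:
    """One material's mass attenuation curve.

    Parameters
    ----------
    name
        Material identifier (unique within a table).
    energies_kev
        Strictly increasing tabulated photon energies, keV.
    mu_over_rho
        Mass attenuation coefficients at those energies, cm^2/g; all > 0.
    """

    name: str
    energies_kev: np.ndarray
    mu_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if not self.name:
            raise ValueError("material name must be nonempty")
        if e.ndim != 1 or e.size < 2:
            raise ValueError(f"{self.name}: need at least 2 energy points")
        if e.size != m.size:
            raise ValueError(f"{self.name}: energy/coefficient length mismatch")
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{self.name}: energies must be strictly increasing")
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            raise ValueError(f"{self.name}: mass attenuation values must be positive and finite")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "mu_over_rho", m)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.energies_kev[0]), float(self.energies_kev[-1])

    def __call__(self, energy_kev: float) -> float:
        """Interpolated mass attenuation at ``energy_kev`` (log-log linear)."""
        lo, hi = self.span
        e = float(energy_kev)
        if e < lo or e > hi:
            raise ExtrapolationError(
                f"{self.name}: energy {e} keV outside tabulated span [{lo}, {hi}] keV"
            )
        return float(
            np.exp(
                np.interp(np.log(e), np.log(self.energies_kev), np.log(self.mu_over_rho))
            )
        )


@dataclass
class AttenuationTable:
    """A named library of :class:`MaterialSpec` curves.

    Water must be present for CT-number conversion; lookups of missing
    materials raise ``KeyError``.
    """

    materials: dict[str, MaterialSpec] = field(default_factory=dict)

    def add(self, spec: MaterialSpec) -> None:
        if spec.name in self.materials:
            raise ValueError(f"duplicate material {spec.name!r}")
        self.materials[spec.name] = spec

    def __getitem__(self, name: str) -> MaterialSpec:
        try:
            return self.materials[name]
        except KeyError:
            raise KeyError(f"material {name!r} not in attenuation table") from None

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def __len__(self) -> int:
        return len(self.materials)

    @property
    def names(self) -> list[str]:
        return sorted(self.materials)

    def mu_water(self, energy_kev: float) -> float:
        """Linear attenuation of water (density 1 g/cm^3) at ``energy_kev``."""
        return self["Water"](energy_kev)


@dataclass(frozen=True)
class EnergyPair:
    """Effective low/high monoenergies standing in for the two spectra, keV."""

    e_low: float
    e_high: float

    def __post_init__(self) -> None:
        if not (0 < self.e_low < self.e_high):
            raise ValueError(
                f"need 0 < e_low < e_high, got ({self.e_low}, {self.e_high})"
            )


REQUIRED_COLUMNS = ("material", "energy_kev", "mu_over_rho")


def load_attenuation_table(path) -> AttenuationTable:
    """Read an attenuation CSV (``material,energy_kev,mu_over_rho``).

    One row per (material, energy). Rows are grouped per material and sorted
    by energy. Duplicate (material, energy) rows, missing columns and
    non-positive coefficients raise :class:`AttenuationFormatError` naming
    the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AttenuationFormatError(f"missing column(s) {missing} in {path}")
    bad = df.index[~np.isfinite(df["mu_over_rho"]) | (df["mu_over_rho"] <= 0)]
    if len(bad):
        raise AttenuationFormatError(
            f"non-positive mass attenuation at row {int(bad[0])} "
            f"({df.loc[bad[0], 'material']!r}, {df.loc[bad[0], 'energy_kev']} keV)"
        )
    dup = df.duplicated(subset=["material", "energy_kev"])
    if dup.any():
        i = int(df.index[dup][0])
        raise AttenuationFormatError(
            f"duplicate (material, energy) at row {i} "
            f"({df.loc[i, 'material']!r}, {df.loc[i, 'energy_kev']} keV)"
        )
    table = AttenuationTable()
    for name, grp in df.groupby("material", sort=True):
        grp = grp.sort_values("energy_kev")
        table.add(
            MaterialSpec(
                name=str(name),
                energies_kev=grp["energy_kev"].to_numpy(float),
                mu_over_rho=grp["mu_over_rho"].to_numpy(float),
            )
        )
    return table


def mass_attenuation(table: AttenuationTable, material: str, energy_kev: float) -> float:
    """Mass attenuation (cm^2/g) of ``material`` at ``energy_kev``.

    Log-log linear interpolation between bracketing tabulated points; exact
    at the knots; raises :class:`ExtrapolationError` outside the span.
    """
    return table[material](energy_kev)


def hu_from_mu(mu, mu_water: float):
    """CT number: ``HU = 1000 * (mu - mu_water) / mu_water``."""
    if mu_water <= 0:
        raise ValueError(f"mu_water must be > 0, got {mu_water}")
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water


def mu_from_hu(hu, mu_water: float):
    """Inverse of :func:`hu_from_mu`."""
    if mu_water <= 0:
        raise ValueError(f"mu_water must be > 0, got {mu_water}")
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def klein_nishina_cross_section(energy_kev: float) -> float:
    """Total Klein-Nishina Compton cross section per electron, cm^2."""
    k = float(energy_kev) / _MEC2_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return float(2 * np.pi * _R_E**2 * (t1 + t2 + t3))


def _electrons_per_gram_fraction(z_eff: float) -> float:
    # Crude Z/A trend: ~0.555 for water-like, lower for high-Z elements.
    return max(0.38, 0.57 - 0.002 * z_eff)


def parametric_attenuation(z_eff: float, density: float, energy_kev: float) -> float:
    """Linear attenuation (1/cm) from a two-term parametric model.

    Photoelectric term proportional to ``Z_eff^3.8 / E^3.2`` plus a
    Klein-Nishina Compton term; strictly decreasing over 40-150 keV and
    linear in density. Intended only to fabricate plausible fixture curves,
    never to stand in for a measured table in scored results.
    """
    if z_eff <= 0:
        raise ValueError(f"z_eff must be > 0, got {z_eff}")
    e = float(energy_kev)
    if not (WORKING_RANGE[0] <= e <= WORKING_RANGE[1]):
        raise ValueError(f"energy {e} keV outside working range {WORKING_RANGE}")
    za = _electrons_per_gram_fraction(z_eff)
    compton = _N_AVOGADRO * za * klein_nishina_cross_section(e)
    photoelectric = _C_PE * za * z_eff**3.8 / e**3.2
    return float(density) * (compton + photoelectric)
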