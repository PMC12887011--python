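"""Energy-dependent photon attenuation of elements, water, air and solutions.

Everything downstream of this module (spectrum filtration, forward
projection, HU calibration) consumes attenuation through three small
surfaces: :func:`kedge_energy`, :func:`mass_attenuation` and
:func:`linear_attenuation`.

Data come from plain-text tables bundled under ``kedgect/data`` (two
columns, keV and cm^2/g; duplicated abscissae at absorption edges — see
``scripts/make_attenuation_tables.py`` for provenance and format).
Interpolation is linear in log(E)-log(mu/rho) and never bridges an edge:
querying exactly at an edge energy returns the above-edge branch.

Solutions are ideal dilute aqueous mixtures: a solute at concentration
``c`` mg/mL adds ``c * 1e-3 [g/cm^3] * (mu/rho)_solute`` to the linear
attenuation of pure water (density 1.0 g/cm^3, volume displacement
neglected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .crosssections import K_EDGE_KEV

__all__ = [
    "AttenuationCurve",
    "ElementRecord",
    "SolutionMaterial",
    "TabulatedMaterial",
    "UnsupportedElementError",
    "get_element",
    "kedge_energy",
    "mass_attenuation",
    "linear_attenuation",
    "water",
    "air",
    "WATER_DENSITY_G_CM3",
    "AIR_DENSITY_G_CM3",
    "TABLE_ELEMENTS",
]

WATER_DENSITY_G_CM3 = 1.0
AIR_DENSITY_G_CM3 = 1.205e-3  # dry air near sea level

#: The 15 insert elements of the study phantom, in atomic-number order.
TABLE_ELEMENTS = ["Ca", "Fe", "I", "Ba", "Sm", "Eu", "Gd", "Tb",
                  "Yb", "Lu", "Ta", "W", "Pt", "Au", "Bi"]

_ATOMIC_NUMBER = {"Al": 13, "Ca": 20, "Fe": 26, "I": 53, "Ba": 56, "Sm": 62,
                  "Eu": 63, "Gd": 64, "Tb": 65, "Yb": 70, "Lu": 71, "Ta": 73,
                  "W": 74, "Pt": 78, "Au": 79, "Bi": 83}

# Elements with no K-edge above the ~1 keV relevance cutoff of this model
# (supported only so that kedge_energy can answer for them).
_NO_EDGE_ELEMENTS = {"H": 1, "C": 6, "N": 7, "O": 8}


class UnsupportedElementError(KeyError):
    """Raised for a chemical symbol this package has no data for."""


@dataclass(frozen=True)
class AttenuationCurve:
    """Tabulated mass attenuation with explicit edge discontinuities.

    ``energies_keV`` is non-decreasing; an absorption edge appears as two
    identical abscissae holding the below- and above-edge values.
    """

    energies_keV: np.ndarray
    mu_over_rho_cm2_per_g: np.ndarray
    _log_e: np.ndarray = field(init=False, repr=False, compare=False)
    _log_mu: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        mu = np.asarray(self.mu_over_rho_cm2_per_g, dtype=float)
        if e.ndim != 1 or e.shape != mu.shape:
            raise ValueError("energies and values must be 1-D and aligned")
        if np.any(np.diff(e) < 0):
            raise ValueError("energy grid must be non-decreasing")
        if np.any(mu <= 0):
            raise ValueError("mass attenuation values must be positive")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "mu_over_rho_cm2_per_g", mu)
        object.__setattr__(self, "_log_e", np.log(e))
        object.__setattr__(self, "_log_mu", np.log(mu))

    @property
    def e_min(self) -> float:
        return float(self.energies_keV[0])

    @property
    def e_max(self) -> float:
        return float(self.energies_keV[-1])

    def __call__(self, energy_keV):
        """Log-log interpolated mu/rho; above-edge branch at an edge energy.

        Accepts a scalar or array; raises ``ValueError`` outside the
        tabulated range.
        """
        e_arr = np.atleast_1d(np.asarray(energy_keV, dtype=float))
        if np.any(e_arr < self.e_min) or np.any(e_arr > self.e_max):
            raise ValueError(
                f"energy outside tabulated range [{self.e_min}, {self.e_max}] keV"
            )
        # side='right' makes a query at a duplicated (edge) abscissa start the
        # interpolation segment at the above-edge row.
        idx = np.searchsorted(self.energies_keV, e_arr, side="right")
        idx = np.clip(idx, 1, len(self.energies_keV) - 1)
        lo, hi = idx - 1, idx
        e0, e1 = self._log_e[lo], self._log_e[hi]
        m0, m1 = self._log_mu[lo], self._log_mu[hi]
        with np.errstate(invalid="ignore"):
            t = np.where(e1 > e0, (np.log(e_arr) - e0) / np.where(e1 > e0, e1 - e0, 1.0), 0.0)
        out = np.exp(m0 + t * (m1 - m0))
        return out if np.ndim(energy_keV) else float(out[0])


@dataclass(frozen=True)
class ElementRecord:
    symbol: str
    Z: int
    kedge_keV: Optional[float]
    curve: AttenuationCurve


@dataclass(frozen=True)
class TabulatedMaterial:
    """Bulk material (water, air) with its own curve and nominal density."""

    name: str
    curve: AttenuationCurve
    density_g_cm3: float

    def linear_attenuation(self, energy_keV):
        return self.curve(energy_keV) * self.density_g_cm3


@dataclass(frozen=True)
class SolutionMaterial:
    """An elemental solute dissolved in water at a fixed concentration."""

    solute: Optional[ElementRecord]
    concentration_mg_per_mL: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.concentration_mg_per_mL < 0:
            raise ValueError("concentration must be non-negative")
        if not self.name:
            label = ("water" if self.solute is None or self.concentration_mg_per_mL == 0
                     else f"{self.solute.symbol} {self.concentration_mg_per_mL:g} mg/mL")
            object.__setattr__(self, "name", label)

    def linear_attenuation(self, energy_keV):
        mu = water().linear_attenuation(energy_keV)
        if self.solute is not None and self.concentration_mg_per_mL > 0:
            c_g_cm3 = self.concentration_mg_per_mL * 1e-3
            mu = mu + c_g_cm3 * self.solute.curve(energy_keV)
        return mu


def _read_table(stem: str) -> AttenuationCurve:
    text = resources.files("kedgect.data").joinpath(f"{stem}.txt").read_text()
    rows = [line.split() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
    data = np.array(rows, dtype=float)
    return AttenuationCurve(data[:, 0], data[:, 1])


_CURVES: dict[str, AttenuationCurve] = {}
_MATERIALS: dict[str, TabulatedMaterial] = {}


def _curve(stem: str) -> AttenuationCurve:
    if stem not in _CURVES:
        _CURVES[stem] = _read_table(stem)
    return _CURVES[stem]


def water() -> TabulatedMaterial:
    if "water" not in _MATERIALS:
        _MATERIALS["water"] = TabulatedMaterial("water", _curve("water"), WATER_DENSITY_G_CM3)
    return _MATERIALS["water"]


def air() -> TabulatedMaterial:
    if "air" not in _MATERIALS:
        _MATERIALS["air"] = TabulatedMaterial("air", _curve("air"), AIR_DENSITY_G_CM3)
    return _MATERIALS["air"]


def get_element(symbol: str) -> ElementRecord:
    """Element record with bundled attenuation curve and K-edge energy."""
    if symbol not in _ATOMIC_NUMBER:
        raise UnsupportedElementError(symbol)
    kedge = K_EDGE_KEV.get(symbol)
    if kedge is not None and kedge < 1.0:
        kedge = None
    return ElementRecord(symbol, _ATOMIC_NUMBER[symbol], kedge, _curve(symbol))


def kedge_energy(element) -> Optional[float]:
    """K-shell absorption edge in keV; None if below the 1 keV cutoff.

    Accepts an :class:`ElementRecord` or a chemical symbol. Symbols of
    light elements without a tracked edge (H, C, N, O) return None.
    """
    if isinstance(element, ElementRecord):
        return element.kedge_keV
    if element in _NO_EDGE_ELEMENTS:
        return None
    return get_element(element).kedge_keV


def mass_attenuation(element, energy_keV):
    """mu/rho in cm^2/g of an element (record or symbol) at ``energy_keV``."""
    rec = element if isinstance(element, ElementRecord) else get_element(element)
    return rec.curve(energy_keV)


def linear_attenuation(material, energy_keV):
    """Linear attenuation (1/cm) of a material object at ``energy_keV``."""
    return material.linear_attenuation(energy_keV)
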