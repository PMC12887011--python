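"""Polychromatic 120 kV x-ray spectrum model and energy-bin bookkeeping.

The tube output is modeled as a Kramers bremsstrahlung continuum (photon
fluence per bin proportional to ``(kV - E) / E``) hardened by an aluminum
filter of configurable equivalent thickness, plus the two strong tungsten
characteristic lines (K-alpha 59.3 keV, K-beta 67.2 keV). The spectrum is
normalized to a per-ray photon budget ``N0`` and represents the fluence a
detector ray records in an air scan.

Energies live on a 1 keV grid of bin left edges from 20 to 119 keV, i.e.
bin ``E`` counts photons in ``[E, E+1)``; the grid partitions [20, 120].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import attenuation

__all__ = ["Spectrum", "EnergyBin", "make_spectrum", "bin_fluence", "mean_energy"]

AL_DENSITY_G_CM3 = 2.699
W_KALPHA_KEV = 59.3
W_KBETA_KEV = 67.2


@dataclass(frozen=True)
class EnergyBin:
    """Half-open detector bin [lo, hi); the terminal bin ending at the tube
    potential is closed on the right by construction of the energy grid."""

    lo_keV: float
    hi_keV: float

    def __post_init__(self) -> None:
        if not self.lo_keV < self.hi_keV:
            raise ValueError("energy bin must have lo < hi")


@dataclass(frozen=True)
class Spectrum:
    """Per-ray air-scan photon fluence on the 1 keV bin grid."""

    energies_keV: np.ndarray  # bin left edges
    fluence: np.ndarray  # photons per ray per bin
    kV: float

    def __post_init__(self) -> None:
        if self.energies_keV.shape != self.fluence.shape:
            raise ValueError("misaligned spectrum arrays")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")

    @property
    def bin_centers_keV(self) -> np.ndarray:
        return self.energies_keV + 0.5

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def to_text(self) -> str:
        rows = "\n".join(f"{e:.1f} {f:.8e}" for e, f in zip(self.energies_keV, self.fluence))
        return f"# kV {self.kV}\n# columns: bin_lo_keV photons\n{rows}\n"

    @classmethod
    def from_text(cls, text: str) -> "Spectrum":
        kv = 120.0
        rows = []
        for line in text.splitlines():
            if line.startswith("# kV"):
                kv = float(line.split()[-1])
            elif line.strip() and not line.startswith("#"):
                rows.append([float(x) for x in line.split()])
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1], kv)


def make_spectrum(
    kV: float = 120.0,
    filtration_mmAl: float = 6.0,
    N0: float = 1e5,
    e_min_keV: float = 20.0,
    kalpha_fraction: float = 0.08,
    kbeta_fraction: float = 0.02,
) -> Spectrum:
    """Filtered Kramers spectrum with tungsten characteristic lines.

    ``filtration_mmAl`` is the total aluminum-equivalent filtration; the
    default 6.0 mm reflects a clinical CT (inherent plus flat filter) and
    puts the mean energy near 58 keV. The characteristic lines carry the
    given fractions of the total output and are only added when the tube
    potential exceeds the tungsten K-edge (69.5 keV).
    """
    if N0 <= 0:
        raise ValueError("photon budget N0 must be positive")
    if filtration_mmAl < 0:
        raise ValueError("filtration must be non-negative")
    edges = np.arange(e_min_keV, 120.0)
    centers = edges + 0.5
    cont = np.clip(kV - centers, 0.0, None) / centers
    if filtration_mmAl > 0:
        al = attenuation.get_element("Al")
        mu_al = al.curve(centers) * AL_DENSITY_G_CM3  # 1/cm
        cont = cont * np.exp(-mu_al * filtration_mmAl * 0.1)
    fluence = cont / cont.sum() * N0
    w_kedge = attenuation.kedge_energy("W")
    if kV > w_kedge:
        line_frac = kalpha_fraction + kbeta_fraction
        fluence *= 1.0 - line_frac
        for e_line, frac in ((W_KALPHA_KEV, kalpha_fraction), (W_KBETA_KEV, kbeta_fraction)):
            fluence[int(np.floor(e_line - e_min_keV))] += frac * N0
    fluence[centers > kV] = 0.0
    fluence *= N0 / fluence.sum()
    return Spectrum(edges, fluence, kV)


def bin_fluence(spectrum: Spectrum, bin: EnergyBin) -> float:
    """Total photons falling in an energy bin ([lo, hi); hi=120 closes the
    terminal bin). Energies above the grid simply contribute nothing."""
    if not (spectrum.energies_keV[0] <= bin.lo_keV < bin.hi_keV):
        raise ValueError("bin outside spectrum support")
    mask = (spectrum.energies_keV >= bin.lo_keV) & (spectrum.energies_keV < bin.hi_keV)
    return float(spectrum.fluence[mask].sum())


def mean_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean photon energy in keV."""
    return float(np.average(spectrum.bin_centers_keV, weights=spectrum.fluence))
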