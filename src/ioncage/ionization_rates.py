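"""Atomic ionization and decay rates — stage (i) of the hybrid model.

Three channels feed the charge-state rate equations:

* **photoionization** — at 7.14 keV absorption by H/C/N/O/S is almost
  entirely K-shell; the rate is the tabulated cross section times the
  instantaneous photon flux,
* **K-hole (Auger) decay** — an inner-shell hole relaxes non-radiatively
  with an effective single rate per element, ejecting a secondary electron;
  the small radiative (fluorescence) branch fills the hole without
  ionization,
* **electron-impact ionization** — trapped plasma electrons knock out
  valence electrons; the cross section follows the Lotz form
  ``sigma(E) = a * ln(E/B) / (E*B)`` for ``E > B`` and the rate is its
  Maxwellian average times the electron density.

The per-element data live in a versioned JSON resource shipped with the
package (``data/rate_table_7p14keV.json``) and can be overridden by path.
Charge-state dependence is applied on load with a screened-hydrogenic
flavour: the photoabsorption cross section scales with the K-shell
occupation ``min(2, Z-q)/2`` and the K binding grows linearly with charge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .constants import MASS_E

__all__ = [
    "ElementData",
    "RateTable",
    "photoionization_rate",
    "impact_ionization_rate",
    "auger_decay_rate",
    "lotz_rate_coefficient",
]

#: Lotz constant, single outer electron: 4.5e-14 cm² eV² = 450 Å² eV²
LOTZ_A = 450.0

_DEFAULT_RESOURCE = "rate_table_7p14keV.json"


@dataclass
class ElementData:
    """Static per-element atomic data at the working photon energy.

    ``photo_cross_section[q]`` (Å²) and ``kshell_binding[q]`` (eV) are
    indexed by charge state ``q = 0 .. Z``; ``valence_binding[q]`` (eV) is
    the lowest ionization energy of charge state ``q`` for ``q = 0 .. Z-1``.
    ``auger_rate`` (fs⁻¹) is the effective total K-hole decay rate and
    ``fluorescence_yield`` its radiative branching fraction.
    """

    symbol: str
    atomic_number: int
    mass: float
    photo_cross_section: np.ndarray
    kshell_binding: np.ndarray
    valence_binding: np.ndarray
    auger_rate: float
    fluorescence_yield: float

    def __post_init__(self) -> None:
        z = self.atomic_number
        if len(self.photo_cross_section) != z + 1:
            raise ValueError(f"{self.symbol}: need {z + 1} cross-section entries")
        if len(self.valence_binding) != z:
            raise ValueError(f"{self.symbol}: need {z} valence binding energies")
        if np.any(np.diff(self.valence_binding) <= 0):
            raise ValueError(f"{self.symbol}: valence binding must increase with q")
        if np.any(self.photo_cross_section < 0):
            raise ValueError(f"{self.symbol}: negative cross section")
        if z < 5 and self.auger_rate != 0.0:
            raise ValueError(f"{self.symbol}: no Auger cascade modeled for Z < 5")

    @classmethod
    def from_record(cls, symbol: str, rec: dict) -> "ElementData":
        z = int(rec["Z"])
        q = np.arange(z + 1)
        # K-shell occupation fraction: 2 electrons while >= 2 remain bound
        k_occ = np.minimum(2, z - q) / 2.0
        sigma = float(rec["sigma_photo"]) * k_occ
        bk = float(rec["kshell_binding"]) + float(rec["kshell_shift_per_charge"]) * q
        return cls(
            symbol=symbol,
            atomic_number=z,
            mass=float(rec["mass"]),
            photo_cross_section=sigma,
            kshell_binding=bk,
            valence_binding=np.asarray(rec["valence_binding"], dtype=float),
            auger_rate=float(rec["auger_rate"]),
            fluorescence_yield=float(rec["fluorescence_yield"]),
        )


@dataclass
class RateTable:
    """Map element symbol -> :class:`ElementData` at one photon energy (keV)."""

    elements: dict
    photon_energy: float
    version: int = 1

    def __getitem__(self, symbol: str) -> ElementData:
        try:
            return self.elements[symbol]
        except KeyError:
            raise KeyError(
                f"element {symbol!r} not covered by the rate table "
                f"(available: {sorted(self.elements)})"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.elements

    @property
    def photon_energy_ev(self) -> float:
        return self.photon_energy * 1000.0

    @classmethod
    def from_json(cls, source) -> "RateTable":
        """Load a table from a path or an open text stream."""
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        elements = {
            sym: ElementData.from_record(sym, rec)
            for sym, rec in doc["elements"].items()
        }
        return cls(
            elements=elements,
            photon_energy=float(doc["photon_energy_keV"]),
            version=int(doc.get("version", 1)),
        )

    @classmethod
    def default(cls) -> "RateTable":
        """The table shipped with the package (7.14 keV)."""
        ref = resources.files("ioncage.data").joinpath(_DEFAULT_RESOURCE)
        with ref.open() as fh:
            return cls.from_json(fh)


def photoionization_rate(elem: ElementData, q: int, flux: float) -> float:
    """Photoionization rate (fs⁻¹) of charge state ``q`` at the given flux.

    ``flux`` is the instantaneous photon flux in photons·Å⁻²·fs⁻¹; the rate
    is simply ``sigma_ph(q) * flux`` and vanishes for a bare nucleus.
    """
    if q >= elem.atomic_number:
        return 0.0
    if flux < 0:
        raise ValueError("flux must be non-negative")
    return float(elem.photo_cross_section[q] * flux)


def auger_decay_rate(elem: ElementData, kholes: int) -> float:
    """Auger (ionizing) K-hole decay rate (fs⁻¹) for ``kholes`` holes.

    Holes decay independently; the radiative branch (fluorescence yield)
    does not ionize and the emitted photon is not re-absorbed.
    """
    if kholes not in (0, 1, 2):
        raise ValueError("kholes must be 0, 1 or 2")
    return kholes * elem.auger_rate * (1.0 - elem.fluorescence_yield)


# 48-point Gauss-Laguerre rule, precomputed once
_GL_X, _GL_W = np.polynomial.laguerre.laggauss(48)


def lotz_rate_coefficient(binding: np.ndarray, t_e: float) -> np.ndarray:
    """Maxwellian-averaged Lotz rate coefficient ⟨σv⟩ (Å³/fs).

    For binding energies ``B`` (eV, any shape) and electron temperature
    ``t_e`` (eV).  Substituting ``E = B + T x`` turns the thermal average

    ``⟨σv⟩ = ∫_B^∞ σ(E) v(E) f(E) dE``

    into a Gauss-Laguerre sum; ``f`` is the Maxwell-Boltzmann energy
    distribution and ``v(E) = sqrt(2E/m_e)``.  The coefficient underflows
    to zero when ``k T_e ≪ B``.
    """
    if t_e <= 0:
        raise ValueError("t_e must be positive")
    b = np.atleast_1d(np.asarray(binding, dtype=float))
    e = b[..., None] + t_e * _GL_X  # (nB, nGL)
    sigma = LOTZ_A * np.log(e / b[..., None]) / (e * b[..., None])
    v = np.sqrt(2.0 * e / MASS_E)
    # f(E) dE with E = B + T x:  2 sqrt(E/pi) T^{-3/2} e^{-E/T} * T dx
    weight = 2.0 * np.sqrt(e / np.pi) * t_e**-0.5 * np.exp(-b[..., None] / t_e)
    out = np.einsum("...k,k->...", sigma * v * weight, _GL_W)
    out = np.where(np.isfinite(out), out, 0.0)
    return out.reshape(np.shape(binding)) if np.ndim(binding) else float(out[0])


def impact_ionization_rate(
    elem: ElementData, q: int, n_e: float, t_e: float
) -> float:
    """Electron-impact ionization rate (fs⁻¹) of charge state ``q``.

    ``n_e`` is the trapped-electron density (Å⁻³), ``t_e`` the electron
    temperature (eV).  Zero for ``n_e = 0`` and for a bare nucleus.
    """
    if n_e < 0:
        raise ValueError("n_e must be non-negative")
    if q >= elem.atomic_number:
        return 0.0
    if n_e == 0.0:
        return 0.0
    coeff = lotz_rate_coefficient(elem.valence_binding[q], t_e)
    return float(n_e * coeff)
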