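"""Continuum plasma model — stage (ii) of the hybrid pipeline.

Mean-field rate equations advance, per element, a real-valued occupation
vector over charge states ``q = 0..Z`` together with a K-hole population.
Three channels move occupation from ``q`` to ``q+1``:

* photoionization (K-shell; creates a K-hole for Z >= 5),
* Auger decay (consumes a K-hole, ejects a secondary electron),
* electron-impact ionization by the trapped thermal electrons.

Every ejected electron is routed to *trapped* or *escaped* by comparing
its birth kinetic energy with the Coulomb barrier of the positively
charged sample, assumed spherical: ``barrier = k_e * Q_net / R``.  Trapped
secondary (Auger and impact) electrons thermalize instantly; their energy
budget defines the electron temperature ``T_e = (2/3) E / N`` and, with
the density, the inverse Debye screening length ``kappa = sqrt(4 pi k_e
n_e / T_e)`` that the ion dynamics consumes.  Coulomb-bound
photoelectrons are kept on a separate non-thermal ledger: a multi-keV
electron needs far longer than the pulse to thermalize, so it contributes
to charge balance but not to the thermal bath (set ``pe_thermalize`` to
fold it in).  There is no recombination in this continuum mode, so
per-atom charge staircases sampled from the populations are monotone.

The rate equations describe one supercell of the (assumed homogeneous)
crystal; the trapping barrier scales the per-cell escaped charge up to the
whole spherical sample via ``sample_scale`` = (sample volume)/(cell
volume), since the barrier is a property of the crystal, not of one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_E
from .ionization_rates import RateTable, lotz_rate_coefficient

__all__ = [
    "ChargeStatePopulations",
    "PlasmaState",
    "RateHistory",
    "advance_rate_equations",
    "solve_rate_equations",
    "electron_fate",
    "screening_parameter",
    "sample_ion_charges",
]


def screening_parameter(n_e: float, t_e: float) -> float:
    """Inverse Debye screening length kappa (Å⁻¹).

    ``kappa = sqrt(4 pi k_e n_e / T_e)`` in the eV-Å unit system, with
    ``n_e`` in Å⁻³ and ``T_e`` in eV; zero for an empty electron gas.
    """
    if n_e == 0.0:
        return 0.0
    if n_e < 0:
        raise ValueError("n_e must be non-negative")
    if t_e <= 0:
        raise ValueError("T_e must be positive when n_e > 0")
    return float(np.sqrt(4.0 * np.pi * K_E * n_e / t_e))


@dataclass
class PlasmaState:
    """Trapped-electron gas state and escape bookkeeping at one instant.

    ``escaped_charge`` is the per-cell escaped-electron count;
    ``sample_scale`` converts it to the net positive charge of the whole
    spherical sample used for the trapping barrier.
    """

    time: float = 0.0
    n_e: float = 0.0
    t_e: float = 0.0
    kappa: float = 0.0
    escaped_charge: float = 0.0
    sample_radius: float = 1000.0  # Å (100 nm nanocrystal)
    sample_scale: float = 1.0
    trapped_count: float = 0.0
    energy: float = 0.0  # thermal-electron energy budget, eV per cell
    cell_volume: float = 1.0  # Å³
    hot_trapped: float = 0.0  # Coulomb-bound photoelectrons, not thermalized
    pe_thermalize: bool = False

    @property
    def net_positive_charge(self) -> float:
        """Net charge (e) of the whole sample sphere."""
        return self.escaped_charge * self.sample_scale

    @property
    def barrier(self) -> float:
        """Coulomb trapping barrier (eV) at the sample radius."""
        return K_E * self.net_positive_charge / self.sample_radius

    def refresh(self) -> None:
        """Recompute the derived fields n_e, T_e, kappa."""
        self.n_e = self.trapped_count / self.cell_volume
        self.t_e = (
            (2.0 / 3.0) * self.energy / self.trapped_count
            if self.trapped_count > 0
            else 0.0
        )
        self.kappa = (
            screening_parameter(self.n_e, self.t_e) if self.t_e > 0 else 0.0
        )


def electron_range(kinetic_energy: float) -> float:
    """Approximate stopping (CSDA-like) range in Å of an electron in
    water/protein-density matter: ``R ≈ 400 * (E/keV)**1.75`` Å.  Sub-keV
    secondaries stop within a few nm; multi-keV photoelectrons outrun a
    100 nm crystal."""
    return 400.0 * (kinetic_energy / 1000.0) ** 1.75


def electron_fate(kinetic_energy: float, plasma: PlasmaState) -> str:
    """Route an ejected electron to ``"trapped"`` or ``"escaped"``.

    An electron is retained if its kinetic energy is below the Coulomb
    barrier of the positively charged sample, or if its collisional
    stopping range is shorter than the sample radius (it cannot reach the
    surface).  A neutral sample has no barrier, so fast electrons escape
    at early times; a zero-energy electron is trapped by any positive
    barrier."""
    if kinetic_energy < 0:
        raise ValueError("kinetic_energy must be non-negative")
    if kinetic_energy < plasma.barrier:
        return "trapped"
    if electron_range(kinetic_energy) < plasma.sample_radius:
        return "trapped"
    return "escaped"


class ChargeStatePopulations:
    """Per-element occupation over charge states plus K-hole populations."""

    def __init__(self, counts: dict, rates: RateTable):
        self.occ: dict[str, np.ndarray] = {}
        self.khole: dict[str, np.ndarray] = {}
        self._rates = rates
        for sym, n in counts.items():
            z = rates[sym].atomic_number
            occ = np.zeros(z + 1)
            occ[0] = float(n)
            self.occ[sym] = occ
            self.khole[sym] = np.zeros(z + 1)

    @classmethod
    def from_cell(cls, cell, rates: RateTable) -> "ChargeStatePopulations":
        return cls(cell.element_counts(), rates)

    def copy(self) -> "ChargeStatePopulations":
        new = object.__new__(ChargeStatePopulations)
        new.occ = {s: v.copy() for s, v in self.occ.items()}
        new.khole = {s: v.copy() for s, v in self.khole.items()}
        new._rates = self._rates
        return new

    def atom_count(self, sym: str) -> float:
        return float(self.occ[sym].sum())

    def mean_charge(self, sym: str) -> float:
        occ = self.occ[sym]
        tot = occ.sum()
        q = np.arange(len(occ))
        return float((q * occ).sum() / tot) if tot > 0 else 0.0

    def total_ion_charge(self) -> float:
        return float(
            sum((np.arange(len(o)) * o).sum() for o in self.occ.values())
        )


def _advance_substep(
    pops: ChargeStatePopulations,
    plasma: PlasmaState,
    rates: RateTable,
    flux: float,
    dt: float,
) -> None:
    """One explicit Euler substep; mutates ``pops`` and ``plasma``."""
    e_ph = rates.photon_energy_ev
    barrier = plasma.barrier
    d_trapped = 0.0
    d_energy = 0.0
    d_escaped = 0.0
    d_hot = 0.0

    for sym, occ in pops.occ.items():
        ed = rates[sym]
        z = ed.atomic_number
        kh = pops.khole[sym]
        q = np.arange(z)

        # --- channel rates (per atom, fs^-1) on states q = 0..Z-1
        r_photo = ed.photo_cross_section[:-1] * flux
        if plasma.n_e > 0.0 and plasma.t_e > 0.0:
            r_impact = plasma.n_e * lotz_rate_coefficient(
                ed.valence_binding, plasma.t_e
            )
        else:
            r_impact = np.zeros(z)

        # exponential (survival-probability) flows: exact for pure decay,
        # positivity-preserving for any substep
        r_tot = r_photo + r_impact
        with np.errstate(divide="ignore", invalid="ignore"):
            loss = occ[:-1] * -np.expm1(-r_tot * dt)
            share = np.where(r_tot > 0, 1.0 / r_tot, 0.0)
        # --- photoionization q -> q+1 (K-shell; creates a hole for Z >= 5)
        flow_p = loss * r_photo * share
        # --- impact ionization q -> q+1 (valence)
        flow_i = loss * r_impact * share
        # --- Auger / fluorescent K-hole decay (needs >= 3 bound electrons)
        can_auger = (z - q) >= 3
        hole_decay = kh[:-1] * -np.expm1(-ed.auger_rate * dt)
        flow_a = np.where(can_auger, hole_decay * (1 - ed.fluorescence_yield), 0.0)
        flow_f = hole_decay * ed.fluorescence_yield

        # holes ride along with impact ionization of their atoms
        with np.errstate(divide="ignore", invalid="ignore"):
            hole_frac = np.where(occ[:-1] > 0, kh[:-1] / occ[:-1], 0.0)
        hole_move = flow_i * np.clip(hole_frac, 0.0, 1.0)

        occ[:-1] -= flow_p + flow_i + flow_a
        occ[1:] += flow_p + flow_i + flow_a
        if z >= 5:
            kh[1:] += flow_p  # fresh K-holes arrive at q+1
        kh[:-1] -= flow_a + flow_f + hole_move
        kh[1:] += hole_move
        np.clip(kh, 0.0, occ, out=kh)

        # --- electron routing & energy budget
        e_pe = e_ph - ed.kshell_binding[:-1]
        for qq in range(z):
            if flow_p[qq] > 0.0:
                if e_pe[qq] < barrier or (
                    electron_range(max(e_pe[qq], 0.0)) < plasma.sample_radius
                ):
                    # Coulomb-bound photoelectron: keV-scale, thermalizes
                    # far too slowly for the pulse unless configured
                    if plasma.pe_thermalize:
                        d_trapped += flow_p[qq]
                        d_energy += flow_p[qq] * max(e_pe[qq], 0.0)
                    else:
                        d_hot += flow_p[qq]
                else:
                    d_escaped += flow_p[qq]
            if flow_a[qq] > 0.0:
                e_aug = max(
                    ed.kshell_binding[qq]
                    - ed.valence_binding[qq]
                    - ed.valence_binding[min(qq + 1, z - 1)],
                    1.0,
                )
                if e_aug < barrier or electron_range(e_aug) < plasma.sample_radius:
                    d_trapped += flow_a[qq]
                    d_energy += flow_a[qq] * e_aug
                else:
                    d_escaped += flow_a[qq]
        # impact ionization: the new electron joins the gas at ~zero energy,
        # the gas pays the binding energy
        d_trapped += flow_i.sum()
        d_energy -= float((flow_i * ed.valence_binding).sum())

    plasma.trapped_count += d_trapped
    plasma.energy = max(plasma.energy + d_energy, 0.0)
    plasma.escaped_charge += d_escaped
    plasma.hot_trapped += d_hot
    plasma.refresh()


def advance_rate_equations(
    pops: ChargeStatePopulations,
    plasma: PlasmaState,
    rates: RateTable,
    flux: float,
    dt: float,
    max_rate_dt: float = 0.2,
):
    """Advance populations and plasma state by ``dt`` (fs) at fixed flux.

    Internally sub-steps so that no channel rate times the substep exceeds
    ``max_rate_dt``, which guarantees non-negative occupations; occupation
    per element is conserved exactly by construction.  Returns the updated
    ``(pops, plasma)`` (the inputs are not modified).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pops = pops.copy()
    plasma = PlasmaState(**vars(plasma))

    def fastest_rate() -> float:
        r = 1e-12
        for sym in pops.occ:
            ed = rates[sym]
            r = max(r, float(ed.photo_cross_section.max() * flux))
            r = max(r, ed.auger_rate)
            if plasma.n_e > 0 and plasma.t_e > 0:
                r = max(
                    r,
                    float(
                        np.max(
                            plasma.n_e
                            * lotz_rate_coefficient(
                                ed.valence_binding, plasma.t_e
                            )
                        )
                    ),
                )
        return r

    remaining = dt
    while remaining > 1e-12:
        sub = min(remaining, max_rate_dt / fastest_rate())
        _advance_substep(pops, plasma, rates, flux, sub)
        remaining -= sub
        if any(np.any(o < -1e-9) for o in pops.occ.values()):
            raise RuntimeError("integration step failure: negative occupation")
    plasma.time += dt
    return pops, plasma


@dataclass
class RateHistory:
    """Time series of populations and plasma state on a uniform grid."""

    times: np.ndarray
    occ: dict  # sym -> (n_t, Z+1)
    n_e: np.ndarray
    t_e: np.ndarray
    kappa: np.ndarray
    escaped: np.ndarray
    trapped: np.ndarray
    hot: np.ndarray | None = None  # Coulomb-bound, non-thermal photoelectrons

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def mean_charge(self, sym: str) -> np.ndarray:
        occ = self.occ[sym]
        q = np.arange(occ.shape[1])
        tot = occ.sum(axis=1)
        return (occ * q).sum(axis=1) / np.where(tot > 0, tot, 1.0)

    def final_mean_charges(self) -> dict:
        return {sym: float(self.mean_charge(sym)[-1]) for sym in self.occ}

    def to_dataframe(self):
        import pandas as pd

        data = {
            "time": self.times,
            "n_e": self.n_e,
            "t_e": self.t_e,
            "kappa": self.kappa,
            "escaped_charge": self.escaped,
        }
        for sym in self.occ:
            data[f"mean_charge_{sym}"] = self.mean_charge(sym)
        return pd.DataFrame(data)


def solve_rate_equations(
    counts: dict,
    rates: RateTable,
    flux_fn,
    t_end: float,
    dt: float = 0.25,
    sample_radius: float = 1000.0,
    cell_volume: float = 14.0**3,
    pe_thermalize: bool = False,
) -> RateHistory:
    """Integrate the rate equations from a cold neutral cell to ``t_end``.

    ``counts`` maps element symbol to the per-cell atom count; ``flux_fn``
    gives the instantaneous photon flux (photons Å⁻² fs⁻¹) at any time.
    ``sample_radius`` sets the spherical trapping geometry; the barrier
    uses the escaped charge of the whole sphere (``sample_scale`` cells).
    Snapshots are recorded every ``dt`` on ``[0, t_end]``.
    """
    pops = ChargeStatePopulations(counts, rates)
    sphere = 4.0 / 3.0 * np.pi * sample_radius**3
    plasma = PlasmaState(
        sample_radius=sample_radius,
        sample_scale=max(sphere / cell_volume, 1.0),
        cell_volume=cell_volume,
        pe_thermalize=pe_thermalize,
    )
    n_t = int(round(t_end / dt)) + 1
    times = np.arange(n_t) * dt
    occ_hist = {s: np.zeros((n_t, len(o))) for s, o in pops.occ.items()}
    n_e = np.zeros(n_t)
    t_e = np.zeros(n_t)
    kap = np.zeros(n_t)
    esc = np.zeros(n_t)
    trp = np.zeros(n_t)
    hot = np.zeros(n_t)

    def record(i):
        for s in pops.occ:
            occ_hist[s][i] = pops.occ[s]
        n_e[i] = plasma.n_e
        t_e[i] = plasma.t_e
        kap[i] = plasma.kappa
        esc[i] = plasma.escaped_charge
        trp[i] = plasma.trapped_count
        hot[i] = plasma.hot_trapped

    record(0)
    # flux is sampled at midpoints of internal chunks <= 0.05 fs so the
    # recording grid dt does not limit accuracy
    n_chunk = max(1, int(np.ceil(dt / 0.05)))
    chunk = dt / n_chunk
    for i in range(1, n_t):
        for c in range(n_chunk):
            flux = float(flux_fn(times[i - 1] + (c + 0.5) * chunk))
            pops, plasma = advance_rate_equations(pops, plasma, rates, flux, chunk)
        record(i)
    return RateHistory(
        times=times,
        occ=occ_hist,
        n_e=n_e,
        t_e=t_e,
        kappa=kap,
        escaped=esc,
        trapped=trp,
        hot=hot,
    )


def sample_ion_charges(history: RateHistory, cell, seed: int) -> np.ndarray:
    """Per-atom integer charge staircases Q_i(t) sampled from populations.

    Uses a quantile coupling: each atom draws one uniform variate ``u`` and
    its charge at time ``t`` is the ``u``-quantile of its element's charge
    distribution at ``t``.  Because ionization only moves occupation
    upward, the distributions are stochastically ordered in time and every
    staircase is monotonically non-decreasing, while the ensemble marginal
    at each instant reproduces the population distribution exactly.

    Returns an ``(n_atoms, n_times)`` integer array on ``history.times``.
    """
    rng = np.random.default_rng(seed)
    n_atoms = cell.n_atoms
    n_t = len(history.times)
    out = np.zeros((n_atoms, n_t), dtype=np.int16)
    elements = cell.elements.astype(str)
    for sym in np.unique(elements):
        if sym not in history.occ:
            raise KeyError(f"populations do not cover element {sym!r}")
        idx = np.flatnonzero(elements == sym)
        occ = history.occ[sym]  # (n_t, Z+1)
        tot = occ.sum(axis=1, keepdims=True)
        cdf = np.cumsum(occ, axis=1) / np.where(tot > 0, tot, 1.0)
        u = rng.random(len(idx))
        # q_i(t) = #{q' : CDF(q') < u}
        q = (cdf[None, :, :] < u[:, None, None]).sum(axis=2)
        out[idx] = q.astype(np.int16)
    return out
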