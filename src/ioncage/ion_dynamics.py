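"""Screened-Coulomb ion dynamics — stage (iii) of the hybrid pipeline.

Ions interact through the Debye-screened electrostatic pair potential

    V_D(r) = k_e * Q_i * Q_j * exp(-kappa * r) / r

plus a short-range collision potential that switches on below the contact
radius ``r_e`` (sum of the covalent radii of the pair),

    V_C(r) = D * (1 - exp(-a * (r - r_e)))**2   for 0 <= r <= r_e,  else 0,

which excludes unphysically close approach of two *ions* (it acts only
when both partners are charged).  Trajectories integrate ``F_i = -sum_j
grad V_ij`` with classical fixed-step RK4 from rest.  In a periodic cell
the pair sum runs over periodic replications; the screening factor
truncates that sum at the distance where ``exp(-kappa r)`` drops below a
tolerance (the nearest-image shell is always kept), so no Ewald machinery
is needed.  Atoms outside the free sphere (fixed at t = 0 around the S-S
midpoint) are held fixed; mobile atoms are wrapped back into the cell on
output.

Per-atom charges are piecewise-constant staircases on the rate-equation
output grid (integer ionization events); ``kappa`` is linearly
interpolated between grid points (a smooth bath property).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import COVALENT_RADIUS, K_E, MASS_U

__all__ = [
    "PairPotentialParams",
    "DynamicsConfig",
    "Trajectory",
    "screened_pair_potential",
    "collision_potential",
    "total_force",
    "total_potential_energy",
    "integrate",
]


@dataclass
class PairPotentialParams:
    """Collision-potential parameters: well depth ``D`` (eV), hardness ``a``
    (Å⁻¹) and per-element contact radii (Å; the pair radius is the sum)."""

    D: float = 27.2
    a: float = 2.0
    radii: dict = field(default_factory=lambda: dict(COVALENT_RADIUS))

    def __post_init__(self) -> None:
        if self.D < 0 or self.a <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("require D >= 0, a > 0, radii > 0")

    def radius_array(self, elements) -> np.ndarray:
        return np.array([self.radii[e] for e in elements], dtype=float)


@dataclass
class DynamicsConfig:
    """Integration controls.

    ``image_cutoff_tolerance`` truncates the periodic replication sum where
    ``exp(-kappa r)`` falls below it; ``cutoff_floor``/``cutoff_max`` clamp
    the resulting interaction range (the floor keeps the collision range
    and the nearest neighbors in play at strong screening).
    ``output_stride`` is the trajectory sampling interval in fs.
    """

    dt: float = 0.01  # fs
    t_end: float = 100.0  # fs
    image_cutoff_tolerance: float = 1e-3
    free_radius: float = 7.0  # Å
    cutoff_floor: float = 5.0  # Å
    cutoff_max: float = 18.0  # Å
    neighbor_skin: float = 2.0  # Å
    output_stride: float = 1.0  # fs
    max_step_displacement: float = 0.5  # Å, instability guard

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.image_cutoff_tolerance < 1.0):
            raise ValueError("image_cutoff_tolerance must be in (0, 1)")


@dataclass
class Trajectory:
    """Sampled trajectory: S-S distance, energy ledger and positions."""

    times: np.ndarray  # fs
    ss_distance: np.ndarray  # Å, minimum-image for periodic cells
    kinetic: np.ndarray  # eV, mobile atoms
    potential: np.ndarray  # eV, pairs involving mobile atoms
    positions: np.ndarray | None = None  # (n_t, n_atoms, 3) if recorded
    elements: np.ndarray | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "ss_distance": self.ss_distance,
                "kinetic": self.kinetic,
                "potential": self.potential,
            }
        )

    def write_xyz(self, path) -> None:
        """Multi-frame XYZ of the recorded positions."""
        if self.positions is None or self.elements is None:
            raise ValueError("trajectory was run without position recording")
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.positions):
                fh.write(f"{frame.shape[0]}\nt = {t:.3f} fs\n")
                for e, p in zip(self.elements, frame):
                    fh.write(f"{e:2s} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")


def screened_pair_potential(qi: float, qj: float, r: float, kappa: float) -> float:
    """Debye-screened Coulomb pair energy (eV) at separation ``r`` (Å)."""
    if r <= 0:
        raise ValueError("r must be positive")
    return K_E * qi * qj * np.exp(-kappa * r) / r


def collision_potential(r: float, D: float, a: float, r_e: float) -> float:
    """Short-range collision energy (eV); zero at and beyond ``r_e``."""
    if r < 0:
        raise ValueError("r must be non-negative")
    if r >= r_e:
        return 0.0
    return D * (1.0 - np.exp(-a * (r - r_e))) ** 2


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _build_neighbors(
    pos, movers, L, periodic, rcut, nbr_j, nbr_shift, starts, max_pairs
):
    """Neighbor list: for each mover, partners and image-shift vectors
    within ``rcut``.  The nearest image is always scanned; additional
    shells are scanned as ``rcut`` demands.  Returns the pair count, or
    -1 on overflow."""
    n = pos.shape[0]
    m = movers.shape[0]
    extra = int(rcut / L) + 1 if periodic else 0
    if extra > 4:
        extra = 4
    count = 0
    rcut2 = rcut * rcut
    for mi in range(m):
        i = movers[mi]
        starts[mi] = count
        for j in range(n):
            if j == i:
                continue
            bx = pos[j, 0] - pos[i, 0]
            by = pos[j, 1] - pos[i, 1]
            bz = pos[j, 2] - pos[i, 2]
            if periodic:
                sx = -L * np.rint(bx / L)
                sy = -L * np.rint(by / L)
                sz = -L * np.rint(bz / L)
                for ox in range(-extra, extra + 1):
                    for oy in range(-extra, extra + 1):
                        for oz in range(-extra, extra + 1):
                            dx = bx + sx + ox * L
                            dy = by + sy + oy * L
                            dz = bz + sz + oz * L
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 <= rcut2 and r2 > 1e-12:
                                if count >= max_pairs:
                                    return -1
                                nbr_j[count] = j
                                nbr_shift[count, 0] = sx + ox * L
                                nbr_shift[count, 1] = sy + oy * L
                                nbr_shift[count, 2] = sz + oz * L
                                count += 1
            else:
                r2 = bx * bx + by * by + bz * bz
                if r2 <= rcut2:
                    if count >= max_pairs:
                        return -1
                    nbr_j[count] = j
                    nbr_shift[count, 0] = 0.0
                    nbr_shift[count, 1] = 0.0
                    nbr_shift[count, 2] = 0.0
                    count += 1
    starts[m] = count
    return count


@njit(cache=True, fastmath=True)
def _forces_on_movers(
    pos, q, movers, nbr_j, nbr_shift, starts, kappa, rcut, D, a, radii, forces
):
    """Fill ``forces`` (m, 3) with -grad V on the mover atoms.

    A neutral atom feels no force (both potential terms require charge on
    both partners), so its row is skipped outright."""
    m = movers.shape[0]
    rcut2 = rcut * rcut
    for mi in range(m):
        fx = 0.0
        fy = 0.0
        fz = 0.0
        i = movers[mi]
        qi = q[i]
        if qi != 0.0:
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            ri = radii[i]
            for p in range(starts[mi], starts[mi + 1]):
                j = nbr_j[p]
                qj = q[j]
                if qj == 0.0:
                    continue
                dx = pos[j, 0] + nbr_shift[p, 0] - xi
                dy = pos[j, 1] + nbr_shift[p, 1] - yi
                dz = pos[j, 2] + nbr_shift[p, 2] - zi
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > rcut2:
                    continue
                r = np.sqrt(r2)
                # dV/dr of the screened Coulomb term
                ex = np.exp(-kappa * r)
                g = -K_E * qi * qj * ex * (1.0 + kappa * r) / r2
                re = ri + radii[j]
                if r < re:
                    ec = np.exp(-a * (r - re))
                    g += 2.0 * D * (1.0 - ec) * a * ec
                # F_i = (dV/dr) * dx_vec / r  (dx points from i to j)
                coef = g / r
                fx += coef * dx
                fy += coef * dy
                fz += coef * dz
        forces[mi, 0] = fx
        forces[mi, 1] = fy
        forces[mi, 2] = fz


@njit(cache=True, fastmath=True)
def _potential_of_movers(
    pos, q, movers, mobile_mask, nbr_j, nbr_shift, starts, kappa, rcut, D, a, radii
):
    """Pair potential energy (eV) over pairs involving mobile atoms.

    Mobile-mobile pairs are weighted 1/2 (each appears in two rows)."""
    m = movers.shape[0]
    rcut2 = rcut * rcut
    pe = 0.0
    for mi in range(m):
        i = movers[mi]
        qi = q[i]
        ri = radii[i]
        if qi == 0.0:
            continue
        for p in range(starts[mi], starts[mi + 1]):
            j = nbr_j[p]
            qj = q[j]
            if qj == 0.0:
                continue
            dx = pos[j, 0] + nbr_shift[p, 0] - pos[i, 0]
            dy = pos[j, 1] + nbr_shift[p, 1] - pos[i, 1]
            dz = pos[j, 2] + nbr_shift[p, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rcut2:
                continue
            r = np.sqrt(r2)
            v = K_E * qi * qj * np.exp(-kappa * r) / r
            re = ri + radii[j]
            if r < re:
                ec = np.exp(-a * (r - re))
                v += D * (1.0 - ec) ** 2
            pe += 0.5 * v if mobile_mask[j] else v
    return pe


@njit(cache=True, fastmath=True)
def _integrate_kernel(
    pos,
    vel,
    inv_mass,
    movers,
    mobile_mask,
    radii,
    q_grid,  # (n_grid, n_atoms), piecewise-constant charges
    kappa_grid,  # (n_grid,)
    grid_dt,
    L,
    periodic,
    dt,
    n_steps,
    record_every,
    tol,
    rcut_floor,
    rcut_max,
    skin,
    D,
    a,
    bridge_i,
    bridge_j,
    max_disp,
    max_pairs,
    out_t,
    out_ss,
    out_ke,
    out_pe,
    out_pos,
    record_pos,
):
    """Fixed-step RK4 through the charge/kappa schedule.  Returns 0 on
    success, 1 on the instability guard, 2 on neighbor-list overflow."""
    n = pos.shape[0]
    m = movers.shape[0]
    n_grid = kappa_grid.shape[0]
    nbr_j = np.empty(max_pairs, dtype=np.int32)
    nbr_shift = np.empty((max_pairs, 3), dtype=np.float64)
    starts = np.empty(m + 1, dtype=np.int64)

    f1 = np.empty((m, 3))
    f2 = np.empty((m, 3))
    f3 = np.empty((m, 3))
    f4 = np.empty((m, 3))
    xtmp = pos.copy()
    v1 = np.empty((m, 3))

    init_moving = False
    for i in range(n):
        if (
            vel[i, 0] != 0.0 or vel[i, 1] != 0.0 or vel[i, 2] != 0.0
        ) and mobile_mask[i]:
            init_moving = True
            break

    rec = 0
    built = False
    rcut_at_build = 0.0
    disp_acc = 0.0
    status = 0

    for step in range(n_steps + 1):
        t = step * dt
        gi = int(t / grid_dt)
        if gi > n_grid - 1:
            gi = n_grid - 1
        frac = t / grid_dt - gi
        if gi < n_grid - 1:
            kappa = kappa_grid[gi] * (1.0 - frac) + kappa_grid[gi + 1] * frac
        else:
            kappa = kappa_grid[n_grid - 1]
        if kappa > 1e-9:
            rcut = -np.log(tol) / kappa
        else:
            rcut = rcut_max
        if rcut < rcut_floor:
            rcut = rcut_floor
        if rcut > rcut_max:
            rcut = rcut_max

        qrow = q_grid[gi]
        any_q = False
        for i in range(n):
            if qrow[i] != 0.0:
                any_q = True
                break
        active = any_q or init_moving or built

        # --- neighbor list upkeep (before recording so PE is current)
        if active and (
            (not built) or disp_acc > 0.5 * skin or rcut > rcut_at_build
        ):
            cnt = _build_neighbors(
                pos,
                movers,
                L,
                periodic,
                rcut + skin,
                nbr_j,
                nbr_shift,
                starts,
                max_pairs,
            )
            if cnt < 0:
                status = 2
                break
            built = True
            rcut_at_build = rcut + skin
            disp_acc = 0.0

        # --- record
        if step % record_every == 0:
            dxs = pos[bridge_j, 0] - pos[bridge_i, 0]
            dys = pos[bridge_j, 1] - pos[bridge_i, 1]
            dzs = pos[bridge_j, 2] - pos[bridge_i, 2]
            if periodic:
                dxs -= L * np.rint(dxs / L)
                dys -= L * np.rint(dys / L)
                dzs -= L * np.rint(dzs / L)
            out_t[rec] = t
            out_ss[rec] = np.sqrt(dxs * dxs + dys * dys + dzs * dzs)
            ke = 0.0
            for mi in range(m):
                i = movers[mi]
                ke += (
                    0.5
                    / inv_mass[i]
                    * (
                        vel[i, 0] * vel[i, 0]
                        + vel[i, 1] * vel[i, 1]
                        + vel[i, 2] * vel[i, 2]
                    )
                )
            out_ke[rec] = ke
            out_pe[rec] = (
                _potential_of_movers(
                    pos,
                    qrow,
                    movers,
                    mobile_mask,
                    nbr_j,
                    nbr_shift,
                    starts,
                    kappa,
                    rcut,
                    D,
                    a,
                    radii,
                )
                if built
                else 0.0
            )
            if record_pos:
                for i in range(n):
                    out_pos[rec, i, 0] = pos[i, 0]
                    out_pos[rec, i, 1] = pos[i, 1]
                    out_pos[rec, i, 2] = pos[i, 2]
            rec += 1
        if step == n_steps:
            break
        if not active:
            continue  # cold, neutral, at rest: nothing can move yet

        half = 0.5 * dt
        _forces_on_movers(
            pos, qrow, movers, nbr_j, nbr_shift, starts, kappa, rcut, D, a, radii, f1
        )
        for mi in range(m):
            i = movers[mi]
            for k in range(3):
                xtmp[i, k] = pos[i, k] + half * vel[i, k]
                v1[mi, k] = vel[i, k] + half * f1[mi, k] * inv_mass[i]
        _forces_on_movers(
            xtmp, qrow, movers, nbr_j, nbr_shift, starts, kappa, rcut, D, a, radii, f2
        )
        for mi in range(m):
            i = movers[mi]
            for k in range(3):
                xtmp[i, k] = pos[i, k] + half * v1[mi, k]
        _forces_on_movers(
            xtmp, qrow, movers, nbr_j, nbr_shift, starts, kappa, rcut, D, a, radii, f3
        )
        for mi in range(m):
            i = movers[mi]
            for k in range(3):
                xtmp[i, k] = pos[i, k] + dt * (
                    vel[i, k] + half * f2[mi, k] * inv_mass[i]
                )
        _forces_on_movers(
            xtmp, qrow, movers, nbr_j, nbr_shift, starts, kappa, rcut, D, a, radii, f4
        )

        step_max = 0.0
        for mi in range(m):
            i = movers[mi]
            im = inv_mass[i]
            d2 = 0.0
            for k in range(3):
                a1 = f1[mi, k] * im
                a2 = f2[mi, k] * im
                a3 = f3[mi, k] * im
                a4 = f4[mi, k] * im
                dxk = dt * vel[i, k] + dt * dt / 6.0 * (a1 + a2 + a3)
                pos[i, k] += dxk
                vel[i, k] += dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
                d2 += dxk * dxk
            if d2 > step_max:
                step_max = d2
        step_max = np.sqrt(step_max)
        if step_max > max_disp:
            status = 1
            break
        disp_acc += step_max

    return status


# ---------------------------------------------------------------------------
# python-level API
# ---------------------------------------------------------------------------


def _pair_capacity(n: int, m: int, L: float, periodic: bool, rcut: float) -> int:
    if not periodic:
        return max(m * n, 4096)
    vol_ratio = 4.19 * rcut**3 / L**3
    per_pair = max(8, int(vol_ratio) + 2)
    return max(m * n * per_pair, 4096)


def _rcut(kappa: float, config: DynamicsConfig) -> float:
    if kappa > 1e-9:
        rcut = -np.log(config.image_cutoff_tolerance) / kappa
    else:
        rcut = config.cutoff_max
    return float(np.clip(rcut, config.cutoff_floor, config.cutoff_max))


def _check_overlaps(cell) -> None:
    pos = cell.positions
    d = pos[:, None, :] - pos[None, :, :]
    if cell.periodic:
        L = cell.edge_length
        d -= L * np.round(d / L)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    i, j = np.unravel_index(np.argmin(r2), r2.shape)
    if r2[i, j] < 1e-6:
        raise ValueError(f"overlapping atoms {i} and {j}")


def _neighbor_setup(cell, movers, rcut):
    n = cell.n_atoms
    L = cell.edge_length if cell.periodic else 1.0
    cap = _pair_capacity(n, len(movers), L, cell.periodic, rcut)
    nbr_j = np.empty(cap, dtype=np.int32)
    nbr_shift = np.empty((cap, 3), dtype=np.float64)
    starts = np.empty(len(movers) + 1, dtype=np.int64)
    pos = np.ascontiguousarray(cell.positions)
    cnt = _build_neighbors(
        pos, movers, L, cell.periodic, rcut, nbr_j, nbr_shift, starts, cap
    )
    if cnt < 0:
        raise RuntimeError("neighbor list overflow")
    return pos, nbr_j, nbr_shift, starts


def total_force(
    cell,
    kappa: float,
    params: PairPotentialParams | None = None,
    config: DynamicsConfig | None = None,
    charges=None,
) -> np.ndarray:
    """Forces (eV/Å) on every atom of ``cell`` (mobile or not) at ``kappa``.

    Analytic gradient of the screened Coulomb plus collision pair
    potentials, summed over periodic images out to the screening cutoff.
    """
    params = params or PairPotentialParams()
    config = config or DynamicsConfig()
    q = np.asarray(cell.charges if charges is None else charges, dtype=float)
    _check_overlaps(cell)
    n = cell.n_atoms
    movers = np.arange(n, dtype=np.int64)
    radii = params.radius_array(cell.elements)
    rcut = _rcut(kappa, config)
    pos, nbr_j, nbr_shift, starts = _neighbor_setup(cell, movers, rcut)
    forces = np.empty((n, 3))
    _forces_on_movers(
        pos,
        q,
        movers,
        nbr_j,
        nbr_shift,
        starts,
        float(kappa),
        rcut,
        params.D,
        params.a,
        radii,
        forces,
    )
    return forces


def total_potential_energy(
    cell,
    kappa: float,
    params: PairPotentialParams | None = None,
    config: DynamicsConfig | None = None,
    charges=None,
) -> float:
    """Total pair potential energy (eV) over all pairs (image-summed)."""
    params = params or PairPotentialParams()
    config = config or DynamicsConfig()
    q = np.asarray(cell.charges if charges is None else charges, dtype=float)
    n = cell.n_atoms
    movers = np.arange(n, dtype=np.int64)
    radii = params.radius_array(cell.elements)
    rcut = _rcut(kappa, config)
    pos, nbr_j, nbr_shift, starts = _neighbor_setup(cell, movers, rcut)
    all_mobile = np.ones(n, dtype=np.bool_)
    return float(
        _potential_of_movers(
            pos,
            q,
            movers,
            all_mobile,
            nbr_j,
            nbr_shift,
            starts,
            float(kappa),
            rcut,
            params.D,
            params.a,
            radii,
        )
    )


def integrate(
    cell,
    charge_trajectories,
    kappa_history,
    params: PairPotentialParams | None = None,
    config: DynamicsConfig | None = None,
    grid_dt: float | None = None,
    record_positions: bool = False,
) -> Trajectory:
    """Integrate the cell through the charge/screening schedule.

    ``charge_trajectories`` is ``(n_atoms, n_grid)`` (piecewise-constant
    per-atom charges) and ``kappa_history`` the matching screening series
    on a uniform grid of spacing ``grid_dt`` (defaults to
    ``t_end / (n_grid - 1)``); scalars/1-column arrays are broadcast as
    frozen values.  Atoms flagged immobile in the cell stay fixed; the
    initial state is taken from the cell (ions start at rest unless the
    cell carries velocities).
    """
    params = params or PairPotentialParams()
    config = config or DynamicsConfig()
    n = cell.n_atoms

    q = np.asarray(charge_trajectories, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    if q.shape[0] != n:
        raise ValueError("charge array must be (n_atoms, n_grid)")
    kappa = np.atleast_1d(np.asarray(kappa_history, dtype=float))
    if len(kappa) == 1:
        kappa = np.full(q.shape[1], kappa[0])
    if len(kappa) != q.shape[1]:
        raise ValueError("kappa grid must match the charge grid")
    n_grid = q.shape[1]
    if grid_dt is None:
        grid_dt = config.t_end / max(n_grid - 1, 1)
    if n_grid > 1 and (n_grid - 1) * grid_dt < config.t_end - 1e-9:
        raise ValueError("charge/kappa histories must cover [0, t_end]")
    q_grid = np.ascontiguousarray(q.T)  # (n_grid, n_atoms)

    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    record_every = max(1, int(round(config.output_stride / dt)))
    n_rec = n_steps // record_every + 1

    pos = np.ascontiguousarray(cell.positions.copy())
    vel = np.ascontiguousarray(cell.velocities.copy())
    inv_mass = 1.0 / (cell.masses * MASS_U)
    movers = np.flatnonzero(cell.mobile).astype(np.int64)
    mobile_mask = np.ascontiguousarray(cell.mobile.astype(np.bool_))
    radii = params.radius_array(cell.elements)
    L = cell.edge_length if cell.periodic else 1.0
    max_pairs = _pair_capacity(
        n, len(movers), L, cell.periodic, config.cutoff_max + config.neighbor_skin
    )

    out_t = np.zeros(n_rec)
    out_ss = np.zeros(n_rec)
    out_ke = np.zeros(n_rec)
    out_pe = np.zeros(n_rec)
    out_pos = np.zeros((n_rec, n, 3)) if record_positions else np.zeros((1, 1, 3))

    status = _integrate_kernel(
        pos,
        vel,
        inv_mass,
        movers,
        mobile_mask,
        radii,
        q_grid,
        np.ascontiguousarray(kappa),
        float(grid_dt),
        L,
        cell.periodic,
        dt,
        n_steps,
        record_every,
        config.image_cutoff_tolerance,
        config.cutoff_floor,
        config.cutoff_max,
        config.neighbor_skin,
        params.D,
        params.a,
        int(cell.bridge[0]),
        int(cell.bridge[1]),
        config.max_step_displacement,
        max_pairs,
        out_t,
        out_ss,
        out_ke,
        out_pe,
        out_pos,
        record_positions,
    )
    if status == 1:
        raise RuntimeError(
            f"integration instability: an atom moved more than "
            f"{config.max_step_displacement} Å in one step; reduce dt"
        )
    if status == 2:
        raise RuntimeError("neighbor list overflow")

    if record_positions and cell.periodic:
        out_pos = np.mod(out_pos, cell.edge_length)
    return Trajectory(
        times=out_t,
        ss_distance=out_ss,
        kinetic=out_ke,
        potential=out_pe,
        positions=out_pos if record_positions else None,
        elements=cell.elements if record_positions else None,
    )
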