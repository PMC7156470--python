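"""Synthetic fixtures: supercell, vacuum disulfide, reference intensities.

The simulator operates on a small periodic "supercell": a 14 Å cube of
solvated-protein matter (~300 atoms with hydrogens counted) containing a
single cystine-like disulfide bridge at its centre.  Everything the
pipeline consumes can be generated here from scratch, so no structure
download is ever required; an optional PDB cut-out reader is provided for
working from a real crystal structure.

Coordinate conventions: Å, cell origin at a corner, each axis spanning the
half-open interval ``[0, edge_length)`` when periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ATOMIC_MASS, COVALENT_RADIUS

__all__ = [
    "AtomSite",
    "SimCell",
    "ReflectionSet",
    "generate_supercell",
    "generate_vacuum_disulfide",
    "cutout_from_pdb",
    "generate_reference_intensities",
    "DEFAULT_LIGHT_FRACTIONS",
]

# atom-count fractions of the light elements in a solvated protein cell
# (≈50/50 protein/water by atom count, hydrogens included); the sulfur
# count is set separately by ``sulfur_fraction``
DEFAULT_LIGHT_FRACTIONS = {"H": 0.58, "C": 0.16, "N": 0.045, "O": 0.215}

# cystine stereochemistry beyond the S-S distance (standard values)
CB_SG_BOND = 1.81  # Å
CB_SG_SG_ANGLE = 104.0  # degrees
CB_SG_SG_CB_DIHEDRAL = 90.0  # degrees


@dataclass
class AtomSite:
    """One ion of the dynamics: element, kinematics and time-dependent charge."""

    element: str
    mass: float  # u
    position: np.ndarray  # (3,) Å
    velocity: np.ndarray  # (3,) Å/fs
    charge: float = 0.0  # elementary charges, >= 0
    mobile: bool = True


class SimCell:
    """A (possibly periodic) cubic cell of atoms with one tracked S-S bridge.

    Stores parallel numpy arrays for speed; :attr:`atoms` materialises the
    per-atom :class:`AtomSite` view.  ``bridge`` is the index pair of the
    tracked disulfide sulfurs; ``free_radius`` is the radius of the mobile
    sphere centred on the S-S midpoint (atoms outside are held fixed by
    the integrator).
    """

    def __init__(
        self,
        edge_length: float,
        periodic: bool,
        elements,
        positions,
        bridge,
        free_radius: float | None = None,
        velocities=None,
        charges=None,
        masses=None,
    ):
        self.edge_length = float(edge_length)
        self.periodic = bool(periodic)
        self.elements = np.asarray(elements, dtype=object)
        self.positions = np.array(positions, dtype=float)
        n = len(self.elements)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_atoms, 3)")
        self.velocities = (
            np.zeros((n, 3)) if velocities is None else np.array(velocities, float)
        )
        self.charges = np.zeros(n) if charges is None else np.array(charges, float)
        if masses is None:
            masses = [ATOMIC_MASS[e] for e in self.elements]
        self.masses = np.asarray(masses, dtype=float)
        self.bridge = (int(bridge[0]), int(bridge[1]))
        if self.bridge[0] == self.bridge[1]:
            raise ValueError("bridge must be two distinct atoms")
        for b in self.bridge:
            if self.elements[b] != "S":
                raise ValueError("tracked bridge atoms must be sulfur")
        if free_radius is None:
            free_radius = self.edge_length / 2.0 if self.periodic else np.inf
        if self.periodic and free_radius > self.edge_length / 2.0 + 1e-9:
            raise ValueError("free_radius must not exceed edge_length/2")
        self.free_radius = float(free_radius)
        if self.periodic:
            if np.any(self.positions < 0) or np.any(
                self.positions >= self.edge_length
            ):
                raise ValueError("periodic cell coordinates must lie in [0, L)")
        self.mobile = self._mobile_mask()

    # -- geometry -----------------------------------------------------------

    def _delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = b - a
        if self.periodic:
            d -= self.edge_length * np.round(d / self.edge_length)
        return d

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def ss_midpoint(self) -> np.ndarray:
        i, j = self.bridge
        return self.positions[i] + 0.5 * self._delta(
            self.positions[i], self.positions[j]
        )

    def ss_distance(self) -> float:
        i, j = self.bridge
        return float(
            np.linalg.norm(self._delta(self.positions[i], self.positions[j]))
        )

    def _mobile_mask(self) -> np.ndarray:
        mid = self.ss_midpoint
        d = self.positions - mid
        if self.periodic:
            d -= self.edge_length * np.round(d / self.edge_length)
        return np.linalg.norm(d, axis=1) <= self.free_radius + 1e-12

    @property
    def atoms(self) -> list:
        return [
            AtomSite(
                element=self.elements[i],
                mass=self.masses[i],
                position=self.positions[i].copy(),
                velocity=self.velocities[i].copy(),
                charge=self.charges[i],
                mobile=bool(self.mobile[i]),
            )
            for i in range(self.n_atoms)
        ]

    def element_counts(self) -> dict:
        sym, cnt = np.unique(self.elements.astype(str), return_counts=True)
        return dict(zip(sym.tolist(), cnt.tolist()))

    # -- I/O ----------------------------------------------------------------

    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.n_atoms), comment]
        for e, p in zip(self.elements, self.positions):
            lines.append(f"{e:2s} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}")
        return "\n".join(lines) + "\n"

    def write_xyz(self, path, comment: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(self.to_xyz(comment))


def _cystine_motif(ss_bond_length: float) -> tuple[list, np.ndarray]:
    """Cβ-Sγ-Sγ-Cβ coordinates centred on the S-S midpoint at the origin."""
    d = ss_bond_length
    s1 = np.array([-d / 2, 0.0, 0.0])
    s2 = np.array([+d / 2, 0.0, 0.0])
    ang = np.deg2rad(180.0 - CB_SG_SG_ANGLE)  # polar angle from S-S axis
    dih = np.deg2rad(CB_SG_SG_CB_DIHEDRAL)
    # C on s1: away from s2, rotated off-axis
    c1 = s1 + CB_SG_BOND * np.array([-np.cos(ang), np.sin(ang), 0.0])
    # C on s2: mirrored, twisted by the dihedral about the S-S axis
    c2 = s2 + CB_SG_BOND * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    elements = ["C", "S", "S", "C"]
    coords = np.array([c1, s1, s2, c2])
    return elements, coords


def _largest_remainder_counts(fractions: dict, total: int) -> dict:
    """Integer counts matching ``fractions`` that sum exactly to ``total``."""
    items = sorted(fractions.items())
    raw = np.array([f for _, f in items], float)
    raw = raw / raw.sum() * total
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(rem)[::-1][: total - base.sum()]:
        base[i] += 1
    return {sym: int(c) for (sym, _), c in zip(items, base)}


def generate_supercell(
    edge_length: float = 14.0,
    target_atom_count: int = 300,
    sulfur_fraction: float = 2.0 / 300.0,
    ss_bond_length: float = 2.08,
    seed: int = 0,
    min_distance: float = 1.0,
    light_fractions: dict | None = None,
    free_radius: float | None = None,
) -> SimCell:
    """Generate the periodic solvated-protein supercell fixture.

    A central cystine motif (Cβ-Sγ-Sγ-Cβ, S-S at ``ss_bond_length``) is
    embedded in randomly placed H/C/N/O atoms at the density implied by
    ``target_atom_count`` atoms in the cube.  Placement enforces, in the
    periodic metric, a pairwise separation of at least
    ``max(min_distance, r_cov_i + r_cov_j)`` — no two atoms ever start
    inside their covalent-contact (collision-potential) radius, as in
    real condensed matter where non-bonded contacts sit at or beyond
    bonded distances.  The sulfur count is ``max(2, round(sulfur_fraction
    * target))``; additional sulfurs beyond the bridge pair are placed
    like light atoms.  Reproducible per seed.
    """
    if edge_length <= 2 * ss_bond_length:
        raise ValueError("edge_length must exceed twice the S-S bond length")
    if not (0.0 < sulfur_fraction <= 0.2):
        raise ValueError("sulfur_fraction must lie in (0, 0.2]")
    if target_atom_count < 4:
        raise ValueError("target_atom_count must be at least 4")
    rng = np.random.default_rng(seed)
    L = float(edge_length)
    centre = np.full(3, L / 2.0)

    motif_el, motif_xyz = _cystine_motif(ss_bond_length)
    motif_xyz = motif_xyz + centre

    n_s_extra = max(2, int(round(sulfur_fraction * target_atom_count))) - 2
    n_random = target_atom_count - 4 - n_s_extra
    fractions = dict(light_fractions or DEFAULT_LIGHT_FRACTIONS)
    counts = _largest_remainder_counts(fractions, max(n_random, 0))
    random_elements = [s for s, c in counts.items() for _ in range(c)]
    random_elements += ["S"] * n_s_extra
    rng.shuffle(random_elements)

    elements = list(motif_el)
    placed = motif_xyz.copy()
    placed_rad = np.array([COVALENT_RADIUS[e] for e in elements])
    for sym in random_elements:
        r_new = COVALENT_RADIUS[sym]
        d_min = np.maximum(min_distance, placed_rad + r_new)
        ok = False
        for _ in range(400):
            cand = rng.uniform(0.0, L, size=3)
            d = placed - cand
            d -= L * np.round(d / L)
            if np.all(np.einsum("ij,ij->i", d, d) >= d_min**2):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"infeasible packing: placed {len(placed)} of "
                f"{target_atom_count} atoms at min distance {min_distance} Å"
            )
        placed = np.vstack([placed, cand])
        placed_rad = np.append(placed_rad, r_new)
        elements.append(sym)

    positions = np.mod(placed, L)
    return SimCell(
        edge_length=L,
        periodic=True,
        elements=elements,
        positions=positions,
        bridge=(1, 2),
        free_radius=free_radius,
    )


def generate_vacuum_disulfide(ss_bond_length: float = 2.08) -> SimCell:
    """Isolated four-atom disulfide moiety in vacuum.

    Non-periodic, all atoms mobile, zero initial velocities, centre of
    mass at the origin (hence zero total momentum).
    """
    if ss_bond_length <= 0:
        raise ValueError("ss_bond_length must be positive")
    elements, coords = _cystine_motif(ss_bond_length)
    masses = np.array([ATOMIC_MASS[e] for e in elements])
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    coords = coords - com
    return SimCell(
        edge_length=np.inf,
        periodic=False,
        elements=elements,
        positions=coords,
        bridge=(1, 2),
        free_radius=np.inf,
    )


def cutout_from_pdb(pdb_source, bridge_selector, edge_length: float) -> SimCell:
    """Cut a cubic cell out of a PDB structure around a disulfide bridge.

    ``bridge_selector`` is a pair ``((chain, resseq), (chain, resseq))``
    naming the two cysteines; the cell of the requested edge is centred on
    the midpoint of their SG atoms.  Atoms outside the cube are discarded
    and coordinates re-wrapped to the ``[0, L)`` corner convention
    (half-open: an atom exactly on the upper boundary is excluded).
    """
    import gemmi

    if hasattr(pdb_source, "read"):
        structure = gemmi.read_pdb_string(pdb_source.read())
    else:
        text = str(pdb_source)
        if "\nATOM" in text or text.startswith(("ATOM", "HETATM", "HEADER")):
            structure = gemmi.read_pdb_string(text)
        else:
            structure = gemmi.read_pdb(text)

    def find_sg(chain_name, resseq):
        for model in structure:
            for chain in model:
                if chain.name != str(chain_name):
                    continue
                for res in chain:
                    if res.seqid.num == int(resseq):
                        for atom in res:
                            if atom.name == "SG":
                                return np.array(
                                    [atom.pos.x, atom.pos.y, atom.pos.z]
                                )
        raise ValueError(
            f"bridge selector {chain_name}:{resseq} has no SG atom in the PDB"
        )

    (c1, r1), (c2, r2) = bridge_selector
    sg1 = find_sg(c1, r1)
    sg2 = find_sg(c2, r2)
    if np.linalg.norm(sg2 - sg1) >= edge_length / 2.0:
        raise ValueError("edge_length too small to contain the bridge")

    mid = 0.5 * (sg1 + sg2)
    lo = mid - edge_length / 2.0

    elements, coords = [], []
    bridge_idx = [None, None]
    model = structure[0]
    for chain in model:
        for res in chain:
            for atom in res:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) - lo
                if np.all(p >= 0.0) and np.all(p < edge_length):
                    sym = atom.element.name
                    elements.append(sym if sym in ATOMIC_MASS else sym)
                    coords.append(p)
                    if atom.name == "SG":
                        if np.allclose(p + lo, sg1):
                            bridge_idx[0] = len(coords) - 1
                        elif np.allclose(p + lo, sg2):
                            bridge_idx[1] = len(coords) - 1
    if None in bridge_idx:
        raise ValueError("bridge sulfurs fell outside the cut-out cell")
    masses = [ATOMIC_MASS.get(e, 12.0) for e in elements]
    return SimCell(
        edge_length=edge_length,
        periodic=True,
        elements=elements,
        positions=np.asarray(coords),
        bridge=tuple(bridge_idx),
        masses=masses,
    )


@dataclass
class ReflectionSet:
    """Reflection records: scattering parameter s = sinθ/λ (Å⁻¹), intensity.

    Optional Miller indices ride along untouched.  Round-trips through a
    CSV with header columns ``s,intensity[,h,k,l]``.
    """

    s: np.ndarray
    intensity: np.ndarray
    hkl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must have matching shapes")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(self.s <= 0):
            raise ValueError("s must be positive for non-origin reflections")

    def __len__(self) -> int:
        return len(self.s)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"s": self.s, "intensity": self.intensity})
        if self.hkl is not None:
            df[["h", "k", "l"]] = np.asarray(self.hkl)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReflectionSet":
        import pandas as pd

        df = pd.read_csv(path)
        hkl = (
            df[["h", "k", "l"]].to_numpy()
            if {"h", "k", "l"} <= set(df.columns)
            else None
        )
        return cls(
            s=df["s"].to_numpy(), intensity=df["intensity"].to_numpy(), hkl=hkl
        )


def generate_reference_intensities(
    n: int,
    wilson_b: float = 20.0,
    s_range: tuple = (0.05, 0.43),
    seed: int = 0,
    scale: float = 100.0,
) -> ReflectionSet:
    """Wilson-distributed (acentric) reference intensities.

    ``s`` is sampled uniformly in reciprocal volume (uniform in s³) over
    ``s_range`` and each intensity is exponential with mean
    ``scale * exp(-2 * wilson_b * s**2)`` — the acentric Wilson law, for
    which the normalized cumulative distribution is ``N(z) = 1 - e^(-z)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = s_range
    if not (0.0 < lo < hi <= 1.0):
        raise ValueError("s_range must lie within (0, 1] Å⁻¹")
    rng = np.random.default_rng(seed)
    s = (rng.uniform(lo**3, hi**3, size=n)) ** (1.0 / 3.0)
    mean = scale * np.exp(-2.0 * wilson_b * s**2)
    intensity = rng.exponential(mean)
    return ReflectionSet(s=s, intensity=intensity)
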