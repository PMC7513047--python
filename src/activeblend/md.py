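"""Two-temperature bead-spring polymer melt dynamics.

Kremer-Grest chains -- purely repulsive shifted Lennard-Jones (WCA) pair
interactions plus FENE bonds -- in a fully periodic box, with each chain
coupled to one of two Langevin thermostats ("hot" or "cold").  Everything is
in reduced Lennard-Jones units: lengths in sigma, energies in epsilon, masses
1, time in tau = sigma * sqrt(m/epsilon), and k_B = 1.

The integrator is the Gronbech-Jensen--Farago (GJF) discretization of
Langevin dynamics, which reduces to velocity Verlet for zero friction and
has the exact Maxwell distribution as the stationary velocity law of a free
particle at any time step.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger("activeblend.md")

#: WCA cutoff in units of sigma: the minimum of the Lennard-Jones potential.
RC_FACTOR = 2.0 ** (1.0 / 6.0)

COLD, HOT = 0, 1
SPECIES_TAGS = {COLD: "C", HOT: "H"}
TAG_TO_SPECIES = {"C": COLD, "H": HOT, "cold": COLD, "hot": HOT}


class OverlapError(RuntimeError):
    """Two particles at (numerically) zero separation: divergent potential."""


class BondOverstretchError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension."""

    def __init__(self, chain: int, bond: int, msg: str | None = None):
        self.chain = chain
        self.bond = bond
        super().__init__(
            msg or f"FENE bond {bond} of chain {chain} reached maximum extension"
        )


class SimulationUnstableError(RuntimeError):
    """Integration blew up; carries the last valid state/trajectory."""

    def __init__(self, msg, last_state=None, trajectory=None):
        self.last_state = last_state
        self.trajectory = trajectory
        super().__init__(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic, fully periodic box with edge lengths in sigma."""

    lengths: np.ndarray

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=np.float64).reshape(3).copy()
        if not np.all(lengths > 0):
            raise ValueError("box lengths must be positive")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        return np.mod(positions, self.lengths)

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.lengths * np.round(d / self.lengths)

    def check_cutoff(self, r: float) -> None:
        """Minimum-image convention requires interaction ranges < L_min/2."""
        if r >= float(self.lengths.min()) / 2.0:
            raise ValueError(
                f"interaction range {r} exceeds half the smallest box length"
            )


@dataclass(frozen=True)
class ForceField:
    """WCA + FENE parameters in reduced units.

    The pair cutoff is tied to sigma (rc = 2^(1/6) sigma exactly) so that the
    shifted potential and its derivative vanish continuously at the cutoff.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    K: float = 30.0
    rmax: float = 1.5

    def __post_init__(self):
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.K <= 0:
            raise ValueError("FENE spring constant must be positive")
        if self.rmax <= self.sigma:
            raise ValueError("FENE maximum extension must exceed sigma")

    @property
    def rc(self) -> float:
        return RC_FACTOR * self.sigma


@dataclass(frozen=True)
class ThermostatPair:
    """Cold and hot Langevin reservoirs sharing one coupling friction zeta."""

    Th: float
    Tc: float = 1.0
    zeta: float = 1.5

    def __post_init__(self):
        if not (self.Th >= self.Tc > 0):
            raise ValueError("need Th >= Tc > 0")
        if self.zeta < 0:
            raise ValueError("friction must be nonnegative")

    def temperature_of(self, species: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(species) == HOT, self.Th, self.Tc)


@dataclass(frozen=True)
class ChainTopology:
    """M linear chains of N monomers each, with one species label per chain."""

    M: int
    N: int
    chain_species: np.ndarray

    def __post_init__(self):
        cs = np.asarray(self.chain_species, dtype=np.int8).reshape(self.M).copy()
        if self.M % 2:
            raise ValueError("chain count M must be even")
        if self.N < 2:
            raise ValueError("chain length N must be at least 2")
        if (cs == HOT).sum() != self.M // 2:
            raise ValueError("exactly M/2 chains must be hot")
        object.__setattr__(self, "chain_species", cs)

    @classmethod
    def alternating(cls, M: int, N: int) -> "ChainTopology":
        # even-index chains hot, odd-index cold: a reproducible 50/50 split
        species = np.where(np.arange(M) % 2 == 0, HOT, COLD).astype(np.int8)
        return cls(M=M, N=N, chain_species=species)

    @property
    def n_particles(self) -> int:
        return self.M * self.N

    @property
    def particle_species(self) -> np.ndarray:
        return np.repeat(self.chain_species, self.N)

    @property
    def particle_chain(self) -> np.ndarray:
        return np.repeat(np.arange(self.M, dtype=np.int32), self.N)

    @property
    def bonds(self) -> np.ndarray:
        i = np.arange(self.n_particles - 1)
        keep = (i + 1) % self.N != 0
        return np.column_stack([i[keep], i[keep] + 1]).astype(np.int64)


def bonds_from_chain_ids(chain_id: np.ndarray) -> np.ndarray:
    """Consecutive-particle bonds implied by equal neighboring chain ids."""
    chain_id = np.asarray(chain_id)
    i = np.arange(chain_id.size - 1)
    keep = chain_id[:-1] == chain_id[1:]
    return np.column_stack([i[keep], i[keep] + 1]).astype(np.int64)


@dataclass
class SystemState:
    """Instantaneous configuration: the unit every kernel and analysis consumes."""

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    chain_id: np.ndarray
    box: SimulationBox
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.asarray(self.species, dtype=np.int8)
        self.chain_id = np.asarray(self.chain_id, dtype=np.int32)
        n = self.positions.shape[0]
        if self.velocities.shape != (n, 3) or self.positions.shape != (n, 3):
            raise ValueError("positions and velocities must be (N, 3)")
        if self.species.shape != (n,) or self.chain_id.shape != (n,):
            raise ValueError("species and chain_id must be length N")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def bonds(self) -> np.ndarray:
        return bonds_from_chain_ids(self.chain_id)

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(),
            self.species.copy(), self.chain_id.copy(), self.box, self.time,
        )

    def validate(self, ff: ForceField) -> None:
        """Check state invariants: bond lengths and species/chain consistency."""
        for chain in np.unique(self.chain_id):
            sp = self.species[self.chain_id == chain]
            if not np.all(sp == sp[0]):
                raise ValueError(f"chain {chain} mixes species labels")
        bonds = self.bonds
        if bonds.size:
            d = self.box.minimum_image(
                self.positions[bonds[:, 0]] - self.positions[bonds[:, 1]]
            )
            r = np.linalg.norm(d, axis=1)
            bad = np.nonzero(r >= ff.rmax)[0]
            if bad.size:
                b = int(bad[0])
                raise BondOverstretchError(int(self.chain_id[bonds[b, 0]]), b)


@dataclass(frozen=True)
class IntegratorConfig:
    dt: float = 0.005
    seed: int = 0
    mass: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.mass != 1.0:
            raise ValueError("reduced units assume unit mass")


@dataclass
class Trajectory:
    """Snapshot ensemble sharing one topology and box."""

    positions: np.ndarray  # (T, N, 3)
    velocities: np.ndarray  # (T, N, 3)
    times: np.ndarray  # (T,)
    species: np.ndarray  # (N,)
    chain_id: np.ndarray  # (N,)
    box: SimulationBox

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def snapshot(self, i: int) -> SystemState:
        return SystemState(
            self.positions[i].copy(), self.velocities[i].copy(),
            self.species, self.chain_id, self.box, float(self.times[i]),
        )

    @classmethod
    def from_states(cls, states: list[SystemState]) -> "Trajectory":
        if not states:
            raise ValueError("empty snapshot list")
        s0 = states[0]
        return cls(
            positions=np.stack([s.positions for s in states]),
            velocities=np.stack([s.velocities for s in states]),
            times=np.array([s.time for s in states], dtype=np.float64),
            species=s0.species.copy(),
            chain_id=s0.chain_id.copy(),
            box=s0.box,
        )


# ---------------------------------------------------------------------------
# Pair and bond kernels
# ---------------------------------------------------------------------------

def wca_energy_force(r, ff: ForceField):
    """Shifted, truncated LJ (WCA) energy and scalar force magnitude at distance r.

    Returns ``(U(r), -dU/dr)``; both vanish continuously at rc = 2^(1/6) sigma.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise OverlapError("pair distance must be positive")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    inside = r < ff.rc
    sr6 = np.zeros_like(r)
    sr6[inside] = (ff.sigma / r[inside]) ** 6
    energy = np.where(inside, 4.0 * ff.epsilon * (sr6 ** 2 - sr6) + ff.epsilon, 0.0)
    force = np.where(inside, 24.0 * ff.epsilon * (2.0 * sr6 ** 2 - sr6) / r, 0.0)
    if scalar:
        return float(energy[0]), float(force[0])
    return energy, force


def fene_energy_force(r, ff: ForceField):
    """FENE bond energy and attractive force magnitude at bond length r.

    Diverges as r -> rmax; r >= rmax raises :class:`BondOverstretchError`.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("bond length must be nonnegative")
    if np.any(r >= ff.rmax):
        raise BondOverstretchError(-1, -1, "bond length at or beyond rmax")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    x = (r / ff.rmax) ** 2
    energy = -0.5 * ff.K * ff.rmax ** 2 * np.log1p(-x)
    force = ff.K * r / (1.0 - x)
    if scalar:
        return float(energy[0]), float(force[0])
    return energy, force


@njit(cache=True, inline="always")
def _pair_ef(r2, eps, sig2, rc, style, soft_a):
    """Pair energy and force factor f/r for WCA (style 0) or soft cosine (style 1)."""
    if style == 0:
        sr2 = sig2 / r2
        sr6 = sr2 * sr2 * sr2
        e = 4.0 * eps * (sr6 * sr6 - sr6) + eps
        fac = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        return e, fac
    r = math.sqrt(r2)
    arg = math.pi * r / rc
    e = soft_a * (1.0 + math.cos(arg))
    fmag = soft_a * math.pi / rc * math.sin(arg)
    return e, fmag / r


@njit(cache=True)
def _pairs_n2(pos, L, rc, eps, sig2, style, soft_a, f):
    n = pos.shape[0]
    rc2 = rc * rc
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L[0] * round(dx / L[0])
            dy -= L[1] * round(dy / L[1])
            dz -= L[2] * round(dz / L[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                ep, fac = _pair_ef(r2, eps, sig2, rc, style, soft_a)
                e += ep
                f[i, 0] += fac * dx
                f[i, 1] += fac * dy
                f[i, 2] += fac * dz
                f[j, 0] -= fac * dx
                f[j, 1] -= fac * dy
                f[j, 2] -= fac * dz
    return e


@njit(cache=True)
def _pairs_cells(pos, L, rc, eps, sig2, style, soft_a, f):
    n = pos.shape[0]
    ncx = int(L[0] / rc)
    ncy = int(L[1] / rc)
    ncz = int(L[2] / rc)
    if ncx < 3 or ncy < 3 or ncz < 3 or n < 64:
        return _pairs_n2(pos, L, rc, eps, sig2, style, soft_a, f)
    rc2 = rc * rc
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / L[0] * ncx)
        cy = int(pos[i, 1] / L[1] * ncy)
        cz = int(pos[i, 2] / L[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    # 13 half-shell neighbor offsets (plus same-cell handled separately)
    offs = np.array([
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ], dtype=np.int64)
    e = 0.0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = head[c]
                while i >= 0:
                    # pairs within the same cell
                    j = nxt[i]
                    while j >= 0:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        dx -= L[0] * round(dx / L[0])
                        dy -= L[1] * round(dy / L[1])
                        dz -= L[2] * round(dz / L[2])
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2:
                            ep, fac = _pair_ef(r2, eps, sig2, rc, style, soft_a)
                            e += ep
                            f[i, 0] += fac * dx
                            f[i, 1] += fac * dy
                            f[i, 2] += fac * dz
                            f[j, 0] -= fac * dx
                            f[j, 1] -= fac * dy
                            f[j, 2] -= fac * dz
                        j = nxt[j]
                    i = nxt[i]
                for k in range(13):
                    nx = (cx + offs[k, 0]) % ncx
                    ny = (cy + offs[k, 1]) % ncy
                    nz = (cz + offs[k, 2]) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    i = head[c]
                    while i >= 0:
                        j = head[c2]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= L[0] * round(dx / L[0])
                            dy -= L[1] * round(dy / L[1])
                            dz -= L[2] * round(dz / L[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2:
                                ep, fac = _pair_ef(r2, eps, sig2, rc, style, soft_a)
                                e += ep
                                f[i, 0] += fac * dx
                                f[i, 1] += fac * dy
                                f[i, 2] += fac * dz
                                f[j, 0] -= fac * dx
                                f[j, 1] -= fac * dy
                                f[j, 2] -= fac * dz
                            j = nxt[j]
                        i = nxt[i]
    return e


@njit(cache=True)
def _bond_forces(pos, L, bonds, K, rmax, f):
    """FENE forces; returns (energy, index of first overstretched bond or -1)."""
    e = 0.0
    rmax2 = rmax * rmax
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L[0] * round(dx / L[0])
        dy -= L[1] * round(dy / L[1])
        dz -= L[2] * round(dz / L[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rmax2:
            return e, b
        x = r2 / rmax2
        e += -0.5 * K * rmax2 * math.log(1.0 - x)
        fac = -K / (1.0 - x)
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz
    return e, -1


@njit(cache=True)
def _forces_raw(pos, L, bonds, eps, sig, rc, K, rmax, style, soft_a):
    f = np.zeros_like(pos)
    e = _pairs_cells(pos, L, rc, eps, sig * sig, style, soft_a, f)
    eb, bad = _bond_forces(pos, L, bonds, K, rmax, f)
    return f, e + eb, bad


@njit(cache=True)
def _build_pairs(pos, L, cutoff):
    """All pairs within `cutoff` (minimum image) via a linked-cell pass."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    ncx = int(L[0] / cutoff)
    ncy = int(L[1] / cutoff)
    ncz = int(L[2] / cutoff)
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3 and n >= 64
    if not use_cells:
        cap = n * (n - 1) // 2
        pairs = np.empty((cap, 2), dtype=np.int64)
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= L[0] * round(dx / L[0])
                dy -= L[1] * round(dy / L[1])
                dz -= L[2] * round(dz / L[2])
                if dx * dx + dy * dy + dz * dz < c2:
                    pairs[k, 0] = i
                    pairs[k, 1] = j
                    k += 1
        return pairs[:k]
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = min(int(pos[i, 0] / L[0] * ncx), ncx - 1)
        cy = min(int(pos[i, 1] / L[1] * ncy), ncy - 1)
        cz = min(int(pos[i, 2] / L[2] * ncz), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    offs = np.array([
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ], dtype=np.int64)
    cap = max(64 * n, 1024)
    pairs = np.empty((cap, 2), dtype=np.int64)
    k = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        dx -= L[0] * round(dx / L[0])
                        dy -= L[1] * round(dy / L[1])
                        dz -= L[2] * round(dz / L[2])
                        if dx * dx + dy * dy + dz * dz < c2:
                            pairs[k, 0] = i
                            pairs[k, 1] = j
                            k += 1
                        j = nxt[j]
                    i = nxt[i]
                for o in range(13):
                    nx = (cx + offs[o, 0]) % ncx
                    ny = (cy + offs[o, 1]) % ncy
                    nz = (cz + offs[o, 2]) % ncz
                    cc = (nx * ncy + ny) * ncz + nz
                    i = head[c]
                    while i >= 0:
                        j = head[cc]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= L[0] * round(dx / L[0])
                            dy -= L[1] * round(dy / L[1])
                            dz -= L[2] * round(dz / L[2])
                            if dx * dx + dy * dy + dz * dz < c2:
                                pairs[k, 0] = i
                                pairs[k, 1] = j
                                k += 1
                            j = nxt[j]
                        i = nxt[i]
    return pairs[:k]


@njit(cache=True)
def _forces_from_pairs(pos, L, pairs, bonds, eps, sig, rc, K, rmax,
                       style, soft_a, f):
    """Forces from a candidate pair list plus bonds; returns (epot, bad_bond)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rc2 = rc * rc
    sig2 = sig * sig
    e = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L[0] * round(dx / L[0])
        dy -= L[1] * round(dy / L[1])
        dz -= L[2] * round(dz / L[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            ep, fac = _pair_ef(r2, eps, sig2, rc, style, soft_a)
            e += ep
            f[i, 0] += fac * dx
            f[i, 1] += fac * dy
            f[i, 2] += fac * dz
            f[j, 0] -= fac * dx
            f[j, 1] -= fac * dy
            f[j, 2] -= fac * dz
    eb, bad = _bond_forces(pos, L, bonds, K, rmax, f)
    return e + eb, bad


@njit(cache=True)
def _min_pair_distance(pos, L, search):
    """Smallest pair distance below `search` (returns `search` if none)."""
    n = pos.shape[0]
    best = search
    f = np.zeros((1, 3))  # unused
    ncx = int(L[0] / search)
    ncy = int(L[1] / search)
    ncz = int(L[2] / search)
    if ncx < 3 or ncy < 3 or ncz < 3 or n < 64:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= L[0] * round(dx / L[0])
                dy -= L[1] * round(dy / L[1])
                dz -= L[2] * round(dz / L[2])
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                if r < best:
                    best = r
        return best
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = min(int(pos[i, 0] / L[0] * ncx), ncx - 1)
        cy = min(int(pos[i, 1] / L[1] * ncy), ncy - 1)
        cz = min(int(pos[i, 2] / L[2] * ncz), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = head[c]
                while i >= 0:
                    for ox in range(-1, 2):
                        for oy in range(-1, 2):
                            for oz in range(-1, 2):
                                nx = (cx + ox) % ncx
                                ny = (cy + oy) % ncy
                                nz = (cz + oz) % ncz
                                c2 = (nx * ncy + ny) * ncz + nz
                                j = head[c2]
                                while j >= 0:
                                    if j > i:
                                        dx = pos[i, 0] - pos[j, 0]
                                        dy = pos[i, 1] - pos[j, 1]
                                        dz = pos[i, 2] - pos[j, 2]
                                        dx -= L[0] * round(dx / L[0])
                                        dy -= L[1] * round(dy / L[1])
                                        dz -= L[2] * round(dz / L[2])
                                        r = math.sqrt(dx * dx + dy * dy + dz * dz)
                                        if r < best:
                                            best = r
                                    j = nxt[j]
                    i = nxt[i]
    return best


@njit(cache=True)
def _like_contact_stats(pos, L, species, chain_id, rc):
    """Per-monomer inter-chain like-species contact fractions within rc.

    Returns (sum of fractions, number of monomers with >=1 inter-chain neighbor).
    """
    n = pos.shape[0]
    rc2 = rc * rc
    like = np.zeros(n, dtype=np.int64)
    total = np.zeros(n, dtype=np.int64)
    ncx = max(int(L[0] / rc), 1)
    ncy = max(int(L[1] / rc), 1)
    ncz = max(int(L[2] / rc), 1)
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3 and n >= 64
    if not use_cells:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if chain_id[i] == chain_id[j]:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= L[0] * round(dx / L[0])
                dy -= L[1] * round(dy / L[1])
                dz -= L[2] * round(dz / L[2])
                if dx * dx + dy * dy + dz * dz < rc2:
                    total[i] += 1
                    total[j] += 1
                    if species[i] == species[j]:
                        like[i] += 1
                        like[j] += 1
    else:
        ncell = ncx * ncy * ncz
        head = np.full(ncell, -1, dtype=np.int64)
        nxt = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            cx = min(int(pos[i, 0] / L[0] * ncx), ncx - 1)
            cy = min(int(pos[i, 1] / L[1] * ncy), ncy - 1)
            cz = min(int(pos[i, 2] / L[2] * ncz), ncz - 1)
            c = (cx * ncy + cy) * ncz + cz
            nxt[i] = head[c]
            head[c] = i
        for cx in range(ncx):
            for cy in range(ncy):
                for cz in range(ncz):
                    c = (cx * ncy + cy) * ncz + cz
                    i = head[c]
                    while i >= 0:
                        for ox in range(-1, 2):
                            for oy in range(-1, 2):
                                for oz in range(-1, 2):
                                    nx = (cx + ox) % ncx
                                    ny = (cy + oy) % ncy
                                    nz = (cz + oz) % ncz
                                    c2 = (nx * ncy + ny) * ncz + nz
                                    j = head[c2]
                                    while j >= 0:
                                        if j > i and chain_id[i] != chain_id[j]:
                                            dx = pos[i, 0] - pos[j, 0]
                                            dy = pos[i, 1] - pos[j, 1]
                                            dz = pos[i, 2] - pos[j, 2]
                                            dx -= L[0] * round(dx / L[0])
                                            dy -= L[1] * round(dy / L[1])
                                            dz -= L[2] * round(dz / L[2])
                                            if dx * dx + dy * dy + dz * dz < rc2:
                                                total[i] += 1
                                                total[j] += 1
                                                if species[i] == species[j]:
                                                    like[i] += 1
                                                    like[j] += 1
                                        j = nxt[j]
                        i = nxt[i]
    fsum = 0.0
    count = 0
    for i in range(n):
        if total[i] > 0:
            fsum += like[i] / total[i]
            count += 1
    return fsum, count


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_gjf_chunk(pos, vel, sd, bonds, L, zeta, dt, noise,
                   eps, sig, rc, K, rmax, style, soft_a):
    """GJF Langevin loop over one noise chunk, in place.

    ``noise`` is (nsteps, n, 3) of unit Gaussians (ignored for zeta = 0);
    ``sd`` the per-particle noise scale sqrt(2 zeta T dt).  Returns
    (status, detail): 0 ok; 1 overstretched bond (detail = bond index);
    2 non-finite forces/overlap (detail = step).
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    skin = 0.3 * sig
    pairs = _build_pairs(pos, L, rc + skin)
    ref = pos.copy()
    f = np.zeros((n, 3))
    f2 = np.zeros((n, 3))
    _, bad = _forces_from_pairs(pos, L, pairs, bonds, eps, sig, rc, K, rmax,
                                style, soft_a, f)
    if bad >= 0:
        return 1, bad
    half = 0.5 * zeta * dt
    a_c = (1.0 - half) / (1.0 + half)
    b_c = 1.0 / (1.0 + half)
    half_skin2 = (0.5 * skin) ** 2
    beta = np.zeros((n, 3))
    for step in range(nsteps):
        if zeta > 0.0:
            for i in range(n):
                beta[i, 0] = sd[i] * noise[step, i, 0]
                beta[i, 1] = sd[i] * noise[step, i, 1]
                beta[i, 2] = sd[i] * noise[step, i, 2]
        moved = 0.0
        for i in range(n):
            for k in range(3):
                pos[i, k] += (b_c * dt * vel[i, k]
                              + 0.5 * b_c * dt * dt * f[i, k]
                              + 0.5 * b_c * dt * beta[i, k])
                pos[i, k] -= L[k] * math.floor(pos[i, k] / L[k])
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            dx -= L[0] * round(dx / L[0])
            dy -= L[1] * round(dy / L[1])
            dz -= L[2] * round(dz / L[2])
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > moved:
                moved = d2
        if moved > half_skin2:
            pairs = _build_pairs(pos, L, rc + skin)
            ref[:, :] = pos
        e2, bad = _forces_from_pairs(pos, L, pairs, bonds, eps, sig, rc, K,
                                     rmax, style, soft_a, f2)
        if bad >= 0:
            return 1, bad
        if not math.isfinite(e2):
            return 2, step
        for i in range(n):
            for k in range(3):
                vel[i, k] = (a_c * vel[i, k]
                             + 0.5 * dt * (a_c * f[i, k] + f2[i, k])
                             + b_c * beta[i, k])
                f[i, k] = f2[i, k]
    return 0, 0


#: noise-generation chunk length (steps); fixed so trajectories are
#: reproducible for a given seed independent of the sampling cadence
_CHUNK = 200


def _integrate(pos, vel, Tpart, bonds, L, zeta, dt, nsteps, rng,
               eps, sig, rc, K, rmax, style=0, soft_a=0.0):
    """Drive the jitted GJF chunks; noise comes from the supplied Generator."""
    n = pos.shape[0]
    sd = np.sqrt(2.0 * zeta * Tpart * dt)
    done = 0
    while done < nsteps:
        m = min(_CHUNK, nsteps - done)
        if zeta > 0.0:
            noise = rng.standard_normal((m, n, 3))
        else:
            noise = np.zeros((m, n, 3))
        status, detail = _run_gjf_chunk(pos, vel, sd, bonds, L, zeta, dt,
                                        noise, eps, sig, rc, K, rmax,
                                        style, soft_a)
        if status != 0:
            return status, detail
        done += m
    return 0, 0


def compute_forces(state: SystemState, ff: ForceField,
                   box: SimulationBox | None = None) -> np.ndarray:
    """Per-particle forces (WCA pairs + FENE bonds) with minimum image."""
    box = box or state.box
    box.check_cutoff(ff.rc)
    box.check_cutoff(ff.rmax)
    f, e, bad = _forces_raw(state.positions, box.lengths, state.bonds,
                            ff.epsilon, ff.sigma, ff.rc, ff.K, ff.rmax, 0, 0.0)
    if bad >= 0:
        raise BondOverstretchError(int(state.chain_id[state.bonds[bad, 0]]), bad)
    if not np.isfinite(e) or not np.all(np.isfinite(f)):
        raise OverlapError("non-finite energy/forces: overlapping particles")
    return f


def potential_energy(state: SystemState, ff: ForceField) -> float:
    """Total potential energy of the configuration."""
    _, e, bad = _forces_raw(state.positions, state.box.lengths, state.bonds,
                            ff.epsilon, ff.sigma, ff.rc, ff.K, ff.rmax, 0, 0.0)
    if bad >= 0:
        raise BondOverstretchError(int(state.chain_id[state.bonds[bad, 0]]), bad)
    return float(e)


def kinetic_energy(state: SystemState) -> float:
    return 0.5 * float(np.sum(state.velocities ** 2))


def langevin_step(state: SystemState, ff: ForceField, thermo: ThermostatPair,
                  cfg: IntegratorConfig, rng: np.random.Generator | None = None,
                  external_force: np.ndarray | None = None) -> SystemState:
    """One GJF Langevin step with species-resolved target temperatures.

    With ``zeta = 0`` the update is exactly velocity Verlet; a noninteracting
    particle relaxes to the Maxwell distribution of its species' reservoir.
    ``external_force`` adds a constant per-particle force (useful for tests
    and simple driving protocols).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dt, zeta = cfg.dt, thermo.zeta
    n = state.n_particles
    L = state.box.lengths

    def total_force(s):
        f = compute_forces(s, ff)
        if external_force is not None:
            f = f + external_force
        return f

    f = total_force(state)
    if zeta > 0:
        Tpart = thermo.temperature_of(state.species).astype(np.float64)
        beta = rng.standard_normal((n, 3)) * np.sqrt(2 * zeta * Tpart * dt)[:, None]
    else:
        beta = np.zeros((n, 3))
    half = 0.5 * zeta * dt
    a_c = (1.0 - half) / (1.0 + half)
    b_c = 1.0 / (1.0 + half)
    new = state.copy()
    new.positions = state.box.wrap(
        state.positions + b_c * dt * state.velocities
        + 0.5 * b_c * dt * dt * f + 0.5 * b_c * dt * beta
    )
    f2 = total_force(new)
    new.velocities = a_c * state.velocities + 0.5 * dt * (a_c * f + f2) + b_c * beta
    new.time = state.time + dt
    return new


def run_steady_state(state: SystemState, ff: ForceField, thermo: ThermostatPair,
                     cfg: IntegratorConfig, duration: float,
                     sample_interval: float,
                     include_initial: bool = False) -> Trajectory:
    """Integrate for `duration` tau, sampling snapshots every `sample_interval`.

    Deterministic for a given ``cfg.seed``: segment noise streams are derived
    from one master generator.  Instability (overstretch / overlap) raises
    :class:`SimulationUnstableError` carrying the last valid state.
    """
    if not (duration >= sample_interval > 0):
        raise ValueError("need duration >= sample_interval > 0")
    state.box.check_cutoff(ff.rc)
    state.box.check_cutoff(ff.rmax)
    seg_steps = int(round(sample_interval / cfg.dt))
    n_samples = int(round(duration / sample_interval))
    master = np.random.default_rng(cfg.seed)
    Tpart = thermo.temperature_of(state.species).astype(np.float64)
    pos = state.positions.copy()
    vel = state.velocities.copy()
    bonds = state.bonds
    states: list[SystemState] = []
    t = state.time
    if include_initial:
        states.append(state.copy())
    for s in range(n_samples):
        status, detail = _integrate(
            pos, vel, Tpart, bonds, state.box.lengths, thermo.zeta, cfg.dt,
            seg_steps, master, ff.epsilon, ff.sigma, ff.rc, ff.K, ff.rmax,
        )
        if status != 0:
            traj = Trajectory.from_states(states) if states else None
            last = states[-1] if states else state
            reason = ("bond overstretch" if status == 1
                      else "non-finite forces (overlap/blow-up)")
            raise SimulationUnstableError(
                f"integration unstable after t={t:.1f} tau: {reason}",
                last_state=last, trajectory=traj,
            )
        t += seg_steps * cfg.dt
        snap = SystemState(pos.copy(), vel.copy(), state.species,
                           state.chain_id, state.box, t)
        states.append(snap)
        logger.info("sample %d/%d at t=%.1f tau", s + 1, n_samples, t)
    return Trajectory.from_states(states)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_melt(M: int, N: int = 40, density: float = 0.85,
                    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    seed: int = 0, ff: ForceField | None = None,
                    dt: float = 0.005, zeta: float = 1.5,
                    pushoff_steps: int = 1000,
                    equil_time: float = 25.0) -> SystemState:
    """Well-mixed equilibrium melt at T = 1 and the requested number density.

    Chains are laid down as random walks with 0.97 sigma bonds, overlaps are
    removed with a ramped soft cosine push-off until no pair sits below
    0.9 sigma, and the melt is then equilibrated with the full force field at
    T = 1 (both thermostats cold).  Even-index chains are labeled hot.
    """
    ff = ff or ForceField()
    if M % 2:
        raise ValueError("chain count M must be even")
    if density <= 0:
        raise ValueError("density must be positive")
    if density > 1.2:
        raise ValueError(f"density {density} too high to place chains")
    topo = ChainTopology.alternating(M, N)
    volume = M * N / density
    aspect = np.asarray(aspect, dtype=np.float64)
    L0 = (volume / np.prod(aspect)) ** (1.0 / 3.0)
    box = SimulationBox(L0 * aspect)
    box.check_cutoff(ff.rc)
    box.check_cutoff(ff.rmax)

    rng = np.random.default_rng(seed)
    pos = np.empty((M * N, 3))
    bond_len = 0.97 * ff.sigma
    for c in range(M):
        steps = rng.standard_normal((N - 1, 3))
        steps *= bond_len / np.linalg.norm(steps, axis=1)[:, None]
        walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        pos[c * N:(c + 1) * N] = walk + rng.random(3) * box.lengths
    pos = box.wrap(pos)
    vel = rng.standard_normal((M * N, 3))  # Maxwell at T = 1

    bonds = topo.bonds
    Tinit = np.ones(M * N)
    # ramped soft push-off; FENE bonds stay on throughout
    n_ramp = 10
    chunk = max(pushoff_steps // n_ramp, 1)
    for k in range(n_ramp):
        amp = 1.0 + (100.0 - 1.0) * (k + 1) / n_ramp
        status, _ = _integrate(pos, vel, Tinit, bonds, box.lengths, zeta, dt,
                               chunk, rng, ff.epsilon, ff.sigma, ff.rc,
                               ff.K, ff.rmax, style=1, soft_a=amp)
        if status != 0:
            raise SimulationUnstableError("push-off failed")
    for attempt in range(30):
        if _min_pair_distance(pos, box.lengths, 0.95 * ff.sigma) >= 0.9 * ff.sigma:
            break
        _integrate(pos, vel, Tinit, bonds, box.lengths, zeta, dt, 100, rng,
                   ff.epsilon, ff.sigma, ff.rc, ff.K, ff.rmax,
                   style=1, soft_a=100.0)
    else:
        raise RuntimeError("push-off could not resolve overlaps below 0.9 sigma")

    equil_steps = int(round(equil_time / dt))
    if equil_steps > 0:
        status, detail = _integrate(pos, vel, Tinit, bonds, box.lengths,
                                    zeta, dt, equil_steps, rng, ff.epsilon,
                                    ff.sigma, ff.rc, ff.K, ff.rmax)
        if status != 0:
            raise SimulationUnstableError("equilibration unstable")
    state = SystemState(pos, vel, topo.particle_species, topo.particle_chain,
                        box, 0.0)
    state.validate(ff)
    logger.info("initialized melt: M=%d N=%d density=%.3f box=%s",
                M, N, density, np.round(box.lengths, 3))
    return state
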