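"""Slab-resolved observables of aligned phase-separated states.

All profiles are resolved along the axis normal to the interface (z after
alignment): densities, mean-square velocities (msv), effective temperatures,
hot number fractions, the msv decomposition into composition-weighted
effective temperatures, pressure-tensor profiles, and per-region chain
gyration statistics.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .md import (
    COLD, HOT, ForceField, SimulationBox, SystemState, Trajectory,
    _like_contact_stats,
)

logger = logging.getLogger("activeblend.profiles")


class AlignmentError(RuntimeError):
    """No detectable interface in any snapshot (mixed state)."""


_SELECTORS = {"all": None, "hot": HOT, "cold": COLD}


def _species_mask(species: np.ndarray, selector: str) -> np.ndarray:
    if selector not in _SELECTORS:
        raise ValueError(f"selector must be one of {sorted(_SELECTORS)}")
    if selector == "all":
        return np.ones(species.shape, dtype=bool)
    return species == _SELECTORS[selector]


# ---------------------------------------------------------------------------
# Grids and profile containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabGrid:
    """Uniform half-open slabs [z, z+dz) along one box axis."""

    length: float
    n_slabs: int = 100
    axis: int = 2

    def __post_init__(self):
        if self.length <= 0 or self.n_slabs < 1:
            raise ValueError("need positive length and at least one slab")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")

    @classmethod
    def for_box(cls, box: SimulationBox, n_slabs: int = 100,
                axis: int = 2) -> "SlabGrid":
        return cls(length=float(box.lengths[axis]), n_slabs=n_slabs, axis=axis)

    @property
    def width(self) -> float:
        return self.length / self.n_slabs

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_slabs + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_slabs) + 0.5) * self.width

    def slab_of(self, coords: np.ndarray) -> np.ndarray:
        idx = np.floor(coords / self.width).astype(np.int64)
        return np.clip(idx, 0, self.n_slabs - 1)


@dataclass
class SlabProfile:
    """Per-slab average of one observable with counts and standard errors."""

    centers: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    counts: np.ndarray
    name: str = ""
    units: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "z_center": self.centers, "value": self.values,
            "stderr": self.stderr, "count": self.counts,
        })


@dataclass
class PressureProfile:
    """Slab-resolved kinetic and virial pressure tensors (epsilon/sigma^3).

    ``anisotropy`` is the Fig.-4-style kinetic quantity
    rho(z) < (v_xx^2 + v_yy^2)/2 - v_zz^2 >.  ``gamma_samples`` holds the
    per-snapshot tension integrals used for the diagnostic uncertainty.
    """

    grid: SlabGrid
    kinetic: np.ndarray  # (n_slabs, 3, 3)
    virial: np.ndarray  # (n_slabs, 3, 3)
    anisotropy: np.ndarray  # (n_slabs,)
    anisotropy_stderr: np.ndarray
    counts: np.ndarray
    gamma_samples: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        return self.kinetic + self.virial

    @property
    def normal(self) -> np.ndarray:
        return self.total[:, 2, 2]

    @property
    def tangential(self) -> np.ndarray:
        return 0.5 * (self.total[:, 0, 0] + self.total[:, 1, 1])


@dataclass
class GyrationStats:
    region: str  # hot | cold | transition
    species: str  # hot | cold
    mean_rg2: float
    std_rg2: float
    n_chains: int


@dataclass
class EffectiveTemperatures:
    """Global species-resolved effective temperatures <v^2>/3, with profiles."""

    hot: float
    cold: float
    hot_profile: SlabProfile | None = None
    cold_profile: SlabProfile | None = None

    @property
    def chi(self) -> float:
        return chi_asymmetry(self.hot, self.cold)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _circular_order(coords: np.ndarray, length: float) -> complex:
    """First circular harmonic of a 1-D particle distribution."""
    angles = 2.0 * np.pi * coords / length
    return complex(np.mean(np.exp(1j * angles)))


def align_snapshots(traj: Trajectory, axis: int | None = None,
                    min_amplitude: float = 0.2) -> Trajectory:
    """Center the hot phase at the box midpoint along the interface normal.

    The normal is the axis with the largest first-harmonic amplitude of the
    hot-monomer distribution (the sharpest species-density crossover); it is
    rotated into z.  Each snapshot is shifted so the circular-mean hot
    position maps to L/2.  Snapshots whose harmonic amplitude falls below
    ``min_amplitude`` carry no detectable interface and are skipped; if all
    are skipped an :class:`AlignmentError` is raised.
    """
    hot = traj.species == HOT
    if not hot.any():
        raise AlignmentError("no hot particles to align on")
    T = len(traj)
    amps = np.zeros((T, 3))
    orders = np.zeros((T, 3), dtype=complex)
    for t in range(T):
        for a in range(3):
            c = _circular_order(traj.positions[t][hot, a],
                                float(traj.box.lengths[a]))
            orders[t, a] = c
            amps[t, a] = abs(c)
    normal = int(np.argmax(amps.mean(axis=0))) if axis is None else axis

    keep, new_pos = [], []
    L = float(traj.box.lengths[normal])
    for t in range(T):
        c = orders[t, normal]
        if abs(c) < min_amplitude:
            logger.info("snapshot %d skipped: no detectable interface "
                        "(amplitude %.3f)", t, abs(c))
            continue
        center = (np.angle(c) % (2.0 * np.pi)) * L / (2.0 * np.pi)
        p = traj.positions[t].copy()
        p[:, normal] = np.mod(p[:, normal] + (0.5 * L - center), L)
        keep.append(t)
        new_pos.append(p)
    if not keep:
        raise AlignmentError("no snapshot has a detectable interface")

    positions = np.stack(new_pos)
    velocities = traj.velocities[keep].copy()
    lengths = traj.box.lengths.copy()
    if normal != 2:
        perm = [0, 1, 2]
        perm[normal], perm[2] = perm[2], perm[normal]
        positions = positions[:, :, perm]
        velocities = velocities[:, :, perm]
        lengths = lengths[perm]
    return Trajectory(positions=positions, velocities=velocities,
                      times=traj.times[keep].copy(), species=traj.species,
                      chain_id=traj.chain_id, box=SimulationBox(lengths))


# ---------------------------------------------------------------------------
# Density / velocity profiles
# ---------------------------------------------------------------------------

def _slab_area(traj: Trajectory, grid: SlabGrid) -> float:
    tang = [a for a in range(3) if a != grid.axis]
    return float(traj.box.lengths[tang[0]] * traj.box.lengths[tang[1]])


def density_profile(traj: Trajectory, grid: SlabGrid,
                    selector: str = "all") -> SlabProfile:
    """Per-slab number density averaged over snapshots.

    The integral over slabs times the slab area reproduces the selected
    particle count exactly, per snapshot.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    mask = _species_mask(traj.species, selector)
    area = _slab_area(traj, grid)
    vol = area * grid.width
    per_snap = np.empty((len(traj), grid.n_slabs))
    for t in range(len(traj)):
        z = traj.positions[t][mask, grid.axis]
        counts = np.bincount(grid.slab_of(z), minlength=grid.n_slabs)
        per_snap[t] = counts / vol
    values = per_snap.mean(axis=0)
    stderr = per_snap.std(axis=0, ddof=0) / math.sqrt(len(traj))
    counts = (per_snap * vol).sum(axis=0)
    return SlabProfile(grid.centers.copy(), values, stderr, counts,
                       name=f"density[{selector}]", units="sigma^-3")


def _slab_msv_sums(traj: Trajectory, grid: SlabGrid, mask: np.ndarray):
    """Per-snapshot, per-slab sums of v^2 and counts for `mask` particles."""
    T = len(traj)
    sums = np.zeros((T, grid.n_slabs))
    counts = np.zeros((T, grid.n_slabs))
    for t in range(T):
        z = traj.positions[t][mask, grid.axis]
        idx = grid.slab_of(z)
        v2 = np.sum(traj.velocities[t][mask] ** 2, axis=1)
        sums[t] = np.bincount(idx, weights=v2, minlength=grid.n_slabs)
        counts[t] = np.bincount(idx, minlength=grid.n_slabs)
    return sums, counts


def _snapshot_mean_profile(per_snap: np.ndarray, counts: np.ndarray,
                           name: str, units: str,
                           grid: SlabGrid) -> SlabProfile:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slabs
        n_valid = np.sum(np.isfinite(per_snap), axis=0)
        values = np.where(n_valid > 0, np.nanmean(per_snap, axis=0), np.nan)
        spread = np.where(n_valid > 0, np.nanstd(per_snap, axis=0), np.nan)
    stderr = spread / np.sqrt(np.maximum(n_valid, 1))
    return SlabProfile(grid.centers.copy(), values, stderr,
                       counts.sum(axis=0), name=name, units=units)


def msv_profile(traj: Trajectory, grid: SlabGrid,
                selector: str = "all") -> SlabProfile:
    """Per-slab mean square velocity over three, <v^2(z)>/3.

    Convention: the slab mean is taken per snapshot and then averaged over
    snapshots (slabs empty in a snapshot are skipped), so that the "all"
    profile equals the composition-weighted effective-temperature profile of
    :func:`msv_decomposition` identically.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    mask = _species_mask(traj.species, selector)
    sums, counts = _slab_msv_sums(traj, grid, mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snap = np.where(counts > 0, sums / (3.0 * counts), np.nan)
    return _snapshot_mean_profile(per_snap, counts, f"msv[{selector}]",
                                  "epsilon", grid)


def effective_temperatures(traj: Trajectory,
                           grid: SlabGrid | None = None
                           ) -> EffectiveTemperatures:
    """Global <v^2>/3 per species pooled over all particles and snapshots."""
    result = {}
    for name, code in (("hot", HOT), ("cold", COLD)):
        mask = traj.species == code
        if not mask.any():
            raise ValueError(f"no {name} particles present")
        # the mean over the 3 components is exactly <v^2>/3
        result[name] = float(np.mean(traj.velocities[:, mask] ** 2))
    eff = EffectiveTemperatures(hot=result["hot"], cold=result["cold"])
    if grid is not None:
        eff.hot_profile = msv_profile(traj, grid, "hot")
        eff.cold_profile = msv_profile(traj, grid, "cold")
    return eff


def chi_asymmetry(theff: float, tceff: float) -> float:
    """Temperature asymmetry chi = (Theff - Tceff)/Tceff."""
    if tceff <= 0:
        raise ValueError("cold effective temperature must be positive")
    return (theff - tceff) / tceff


def msv_decomposition(traj: Trajectory, grid: SlabGrid
                      ) -> tuple[SlabProfile, SlabProfile, SlabProfile]:
    """Decompose the msv profile into composition-weighted effective temperatures.

    Returns ``(weighted, factorized, difference)`` where per slab

    * weighted  = < Theff*phi_h + Tceff*(1 - phi_h) >  (equals the msv exactly),
    * factorized = <Theff><phi_h> + <Tceff>(1 - <phi_h>),
    * difference = weighted - factorized, the composition/velocity correlation.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    hsums, hcounts = _slab_msv_sums(traj, grid, traj.species == HOT)
    csums, ccounts = _slab_msv_sums(traj, grid, traj.species == COLD)
    tot_counts = hcounts + ccounts
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted_ts = np.where(tot_counts > 0,
                               (hsums + csums) / (3.0 * tot_counts), np.nan)
        th_ts = np.where(hcounts > 0, hsums / (3.0 * hcounts), np.nan)
        tc_ts = np.where(ccounts > 0, csums / (3.0 * ccounts), np.nan)
        phi_ts = np.where(tot_counts > 0, hcounts / tot_counts, np.nan)

    weighted = _snapshot_mean_profile(weighted_ts, tot_counts,
                                      "msv_weighted", "epsilon", grid)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slabs
        th = np.nanmean(th_ts, axis=0)
        tc = np.nanmean(tc_ts, axis=0)
        phi = np.nanmean(phi_ts, axis=0)
    th = np.where(np.isnan(th) & (phi == 0), 0.0, th)
    tc = np.where(np.isnan(tc) & (phi == 1), 0.0, tc)
    fact_values = th * phi + tc * (1.0 - phi)
    factorized = SlabProfile(grid.centers.copy(), fact_values,
                             np.full(grid.n_slabs, np.nan),
                             tot_counts.sum(axis=0),
                             name="msv_factorized", units="epsilon")
    difference = SlabProfile(grid.centers.copy(),
                             weighted.values - fact_values,
                             weighted.stderr.copy(),
                             tot_counts.sum(axis=0),
                             name="msv_correlation", units="epsilon")
    return weighted, factorized, difference


def number_fraction_profile(traj: Trajectory, grid: SlabGrid) -> SlabProfile:
    """Per-slab hot-monomer number fraction phi_h(z)."""
    _, hcounts = _slab_msv_sums(traj, grid, traj.species == HOT)
    _, ccounts = _slab_msv_sums(traj, grid, traj.species == COLD)
    tot = hcounts + ccounts
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_ts = np.where(tot > 0, hcounts / tot, np.nan)
    return _snapshot_mean_profile(phi_ts, tot, "phi_h", "", grid)


# ---------------------------------------------------------------------------
# Order parameter
# ---------------------------------------------------------------------------

def order_parameter_phi(state: SystemState, ff: ForceField | None = None,
                        rc: float | None = None) -> float:
    """Demixing order parameter Phi = 2x - 1.

    x is the like-species fraction of inter-chain neighbors within rc,
    averaged over monomers that have at least one inter-chain neighbor
    (monomer-weighted).  Phi = 1 for fully separated, 0 for a mixed state.
    """
    ff = ff or ForceField()
    rc = ff.rc if rc is None else rc
    fsum, count = _like_contact_stats(state.positions, state.box.lengths,
                                      state.species, state.chain_id, rc)
    if count == 0:
        raise ValueError("no inter-chain contacts within rc (dilute input)")
    x = fsum / count
    return 2.0 * x - 1.0


# ---------------------------------------------------------------------------
# Pressure profiles
# ---------------------------------------------------------------------------

@njit(cache=True)
def _virial_slab_kernel(pos, L, bonds, n_slabs, area, eps, sig, rc, K, rmax,
                        out):
    """Accumulate (r (x) F)/2A onto slabs whose mid-plane each pair crosses.

    Convention as printed in the source formula: every (unordered) pair whose
    minimum-image segment crosses the mid-plane of a slab contributes its full
    dyad (r (x) F)/(2 A) to that slab.
    """
    n = pos.shape[0]
    dz_slab = L[2] / n_slabs
    rc2 = rc * rc
    sig2 = sig * sig
    rmax2 = rmax * rmax
    # nonbonded pairs, O(N^2); callers pass modest snapshot sizes
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dzz = pos[i, 2] - pos[j, 2]
            dx -= L[0] * round(dx / L[0])
            dy -= L[1] * round(dy / L[1])
            dzz -= L[2] * round(dzz / L[2])
            r2 = dx * dx + dy * dy + dzz * dzz
            if r2 < rc2:
                sr2 = sig2 / r2
                sr6 = sr2 * sr2 * sr2
                fac = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                _add_pair_dyad(out, n_slabs, dz_slab, area, L,
                               pos[i, 2], dx, dy, dzz, fac)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dzz = pos[i, 2] - pos[j, 2]
        dx -= L[0] * round(dx / L[0])
        dy -= L[1] * round(dy / L[1])
        dzz -= L[2] * round(dzz / L[2])
        r2 = dx * dx + dy * dy + dzz * dzz
        if r2 >= rmax2:
            continue
        fac = -K / (1.0 - r2 / rmax2)
        _add_pair_dyad(out, n_slabs, dz_slab, area, L,
                       pos[i, 2], dx, dy, dzz, fac)


@njit(cache=True, inline="always")
def _add_pair_dyad(out, n_slabs, dz_slab, area, L, zi, dx, dy, dzz, fac):
    """Add (r (x) F)/2A to every slab whose mid-plane the segment crosses."""
    # segment endpoints in unwrapped z: particle i at zi, partner at zi - dzz
    zlo = zi - dzz if dzz > 0 else zi
    zhi = zi if dzz > 0 else zi - dzz
    if zhi <= zlo:
        return
    # mid-planes at (p + 0.5) * dz_slab for integer p (periodic images)
    p0 = int(math.floor((zlo - 0.5 * dz_slab) / dz_slab)) + 1
    p1 = int(math.floor((zhi - 0.5 * dz_slab) / dz_slab))
    if p1 < p0:
        return
    rx = dx
    ry = dy
    rz = dzz
    fx = fac * dx
    fy = fac * dy
    fz = fac * dzz
    inv2a = 1.0 / (2.0 * area)
    for p in range(p0, p1 + 1):
        s = p % n_slabs
        out[s, 0, 0] += rx * fx * inv2a
        out[s, 0, 1] += rx * fy * inv2a
        out[s, 0, 2] += rx * fz * inv2a
        out[s, 1, 0] += ry * fx * inv2a
        out[s, 1, 1] += ry * fy * inv2a
        out[s, 1, 2] += ry * fz * inv2a
        out[s, 2, 0] += rz * fx * inv2a
        out[s, 2, 1] += rz * fy * inv2a
        out[s, 2, 2] += rz * fz * inv2a


def pressure_profiles(traj: Trajectory, grid: SlabGrid,
                      ff: ForceField | None = None,
                      kinetic_mode: str = "per_component",
                      include_virial: bool = True) -> PressureProfile:
    """Slab-resolved pressure tensor: kinetic part plus crossing-pair virial.

    The kinetic part defaults to the per-component form rho(z)<v_i v_j>
    (diagonal rho*T for Maxwell velocities); ``kinetic_mode='printed'``
    applies the literal extra factor 1/3.  The virial assigns each pair
    crossing a slab mid-plane its dyad (r (x) F)/2A (a diagnostic
    convention; see the methods note).
    """
    if grid.axis != 2:
        raise ValueError("pressure profiles require the interface normal on z")
    if grid.width <= 0:
        raise ValueError("slab width too small for mid-plane bookkeeping")
    ff = ff or ForceField()
    T = len(traj)
    if T == 0:
        raise ValueError("empty trajectory")
    area = _slab_area(traj, grid)
    slab_vol = area * grid.width
    n = grid.n_slabs

    kin_sum = np.zeros((n, 3, 3))
    aniso_ts = np.full((T, n), np.nan)
    counts = np.zeros(n)
    gamma_samples = np.empty(T)
    bonds = traj.snapshot(0).bonds
    L = traj.box.lengths
    factor = 1.0 / 3.0 if kinetic_mode == "printed" else 1.0
    if kinetic_mode not in ("printed", "per_component"):
        raise ValueError("kinetic_mode must be 'per_component' or 'printed'")

    for t in range(T):
        z = traj.positions[t][:, 2]
        idx = grid.slab_of(z)
        v = traj.velocities[t]
        kin_t = np.zeros((n, 3, 3))
        for i in range(3):
            for j in range(i, 3):
                w = v[:, i] * v[:, j]
                s = np.bincount(idx, weights=w, minlength=n)
                kin_t[:, i, j] += s
                if i != j:
                    kin_t[:, j, i] += s
        cnt = np.bincount(idx, minlength=n)
        counts += cnt
        aniso_w = 0.5 * (v[:, 0] ** 2 + v[:, 1] ** 2) - v[:, 2] ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            aniso_ts[t] = np.bincount(idx, weights=aniso_w, minlength=n) / slab_vol
        kin_sum += kin_t

        vir_t = np.zeros((n, 3, 3))
        if include_virial:
            _virial_slab_kernel(traj.positions[t], L, bonds, n, area,
                                ff.epsilon, ff.sigma, ff.rc, ff.K, ff.rmax,
                                vir_t)
        vir_sum = vir_t if t == 0 else vir_sum + vir_t
        tot_t = kin_t * (factor / slab_vol) + vir_t
        pn = tot_t[:, 2, 2]
        pt = 0.5 * (tot_t[:, 0, 0] + tot_t[:, 1, 1])
        gamma_samples[t] = 0.5 * np.sum(pn - pt) * grid.width

    kinetic = kin_sum * (factor / (slab_vol * T))
    virial = vir_sum / T
    aniso = np.nanmean(aniso_ts, axis=0)
    aniso_err = np.nanstd(aniso_ts, axis=0) / math.sqrt(T)
    return PressureProfile(grid=grid, kinetic=kinetic, virial=virial,
                           anisotropy=aniso, anisotropy_stderr=aniso_err,
                           counts=counts, gamma_samples=gamma_samples)


def tension_integral(pp: PressureProfile) -> tuple[float, float]:
    """Diagnostic interfacial-tension integral gamma = 1/2 int (p_N - p_T) dz.

    Returns (gamma, uncertainty); the uncertainty is the standard error over
    per-snapshot integrals when available.  The full-tensor profile is too
    noisy to make this a converged estimator; it is reported as a diagnostic
    only.
    """
    integrand = pp.normal - pp.tangential
    gamma = 0.5 * float(np.sum(integrand) * pp.grid.width)
    if pp.gamma_samples is not None and pp.gamma_samples.size > 1:
        err = float(pp.gamma_samples.std(ddof=1)
                    / math.sqrt(pp.gamma_samples.size))
    else:
        err = float("nan")
    return gamma, err


# ---------------------------------------------------------------------------
# Gyration radii by region
# ---------------------------------------------------------------------------

def squared_gyration(chain_positions: np.ndarray) -> float:
    """Rg^2 of one chain given unwrapped monomer coordinates."""
    com = chain_positions.mean(axis=0)
    return float(np.mean(np.sum((chain_positions - com) ** 2, axis=1)))


def _unwrap_chain(pos: np.ndarray, box: SimulationBox) -> np.ndarray:
    disp = box.minimum_image(np.diff(pos, axis=0))
    return np.vstack([pos[0], pos[0] + np.cumsum(disp, axis=0)])


def _circular_distance(a: float, b: float, L: float) -> float:
    d = abs(a - b) % L
    return min(d, L - d)


def gyration_by_region(traj: Trajectory, interfaces: tuple[float, float],
                       width: float) -> list[GyrationStats]:
    """Mean squared gyration radius by (phase region, species).

    Chains are assigned by the z of their center of mass: within ``width`` of
    either interface -> transition; between the interfaces (the region
    containing the aligned hot-phase center at L/2) -> hot; otherwise cold.
    Region/species cells with no chains are omitted.
    """
    z1, z2 = sorted(interfaces)
    Lz = float(traj.box.lengths[2])
    records: dict[tuple[str, str], list[float]] = {}
    for t in range(len(traj)):
        pos = traj.positions[t]
        for chain in np.unique(traj.chain_id):
            sel = traj.chain_id == chain
            unwrapped = _unwrap_chain(pos[sel], traj.box)
            rg2 = squared_gyration(unwrapped)
            com_z = float(np.mod(unwrapped.mean(axis=0)[2], Lz))
            d = min(_circular_distance(com_z, z1, Lz),
                    _circular_distance(com_z, z2, Lz))
            if d <= width:
                region = "transition"
            elif z1 < com_z < z2:
                region = "hot"
            else:
                region = "cold"
            species = "hot" if traj.species[sel][0] == HOT else "cold"
            records.setdefault((region, species), []).append(rg2)
    stats = []
    for (region, species), values in sorted(records.items()):
        arr = np.asarray(values)
        stats.append(GyrationStats(region=region, species=species,
                                   mean_rg2=float(arr.mean()),
                                   std_rg2=float(arr.std(ddof=1))
                                   if arr.size > 1 else 0.0,
                                   n_chains=arr.size))
    return stats
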