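"""Seeded synthetic generators for every analysis operation.

These make the toolkit testable without running molecular dynamics:
two-phase particle configurations with Maxwell velocity subsets and
optional interface corrugation, Gaussian q^-2 height-field ensembles,
first-order autoregressive mode series, and critical-curve families
(power-law binodal differences, quadratic-to-plateau entropy production,
crossing cumulant families) with known ground truth.

Fixture chains are label-topological only -- contiguous blocks of N labels
within each species, not mechanically relaxed -- which suffices for the
order parameter, profiles, cumulants and interface analyses (none of which
evaluate bonded forces).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .capillary import HeightField
from .criticality import CriticalCurve
from .md import COLD, HOT, SimulationBox, SystemState

# Critical-curve defaults reproduce the published study conditions: the
# three-parameter binodal fit (A, chi*, beta') = (0.143 sigma^-3, 0.36,
# 0.47), density-difference noise 0.02 sigma^-3, entropy-production
# crossover chi* = 0.43, and cumulant crossings pinned near level 2.0.
DRHO_AMPLITUDE = 0.143
DRHO_CHI_STAR = 0.36
DRHO_BETA = 0.47
DRHO_NOISE = 0.02
ENTROPY_CHI_STAR = 0.43
CUMULANT_LEVEL = 2.0


@dataclass(frozen=True)
class TwoPhaseSpec:
    """Blueprint of a phase-separated slab configuration.

    The hot phase occupies z in (z1, z2) (centered in the box when built for
    alignment round trips); densities, species purities and Maxwell
    temperatures are set per phase.  ``width`` smooths both the density and
    composition crossovers with a tanh profile; ``corrugation`` displaces
    the dividing surfaces by sum of a*cos(2 pi (n x + m y)/L) modes.
    """

    box: tuple[float, float, float]
    rho_hot_phase: float = 0.78
    rho_cold_phase: float = 0.92
    interfaces: tuple[float, float] = (0.0, 0.0)  # z1 < z2; 0,0 -> quarter points
    width: float = 0.0
    purity_hot_phase: float = 1.0
    purity_cold_phase: float = 1.0
    T_hot_species: float = 2.6
    T_cold_species: float = 1.2
    corrugation: tuple[tuple[int, int, float], ...] = ()
    chain_length: int = 40
    enforce_equal_composition: bool = False

    def __post_init__(self):
        if self.rho_hot_phase < 0 or self.rho_cold_phase < 0:
            raise ValueError("phase densities must be nonnegative")
        for p in (self.purity_hot_phase, self.purity_cold_phase):
            if not 0.5 <= p <= 1.0:
                raise ValueError("phase purities must lie in [0.5, 1]")

    @property
    def z12(self) -> tuple[float, float]:
        z1, z2 = self.interfaces
        if z1 == z2 == 0.0:
            Lz = self.box[2]
            return 0.25 * Lz, 0.75 * Lz
        if not z1 < z2:
            raise ValueError("interfaces must satisfy z1 < z2")
        return z1, z2


@dataclass(frozen=True)
class SpectrumSpec:
    """Blueprint of a capillary height-field ensemble with known stiffness."""

    L: float
    gamma_beta: float
    nB: int
    n_snapshots: int
    seed: int = 0

    def __post_init__(self):
        if self.gamma_beta <= 0:
            raise ValueError("stiffness must be positive")
        if self.nB < 4:
            raise ValueError("need at least a 4x4 block grid")


def _phase_indicator(z, z1, z2, width):
    """1 inside the hot slab (z1, z2), 0 outside, tanh-smoothed by `width`."""
    if width <= 0:
        return ((z > z1) & (z < z2)).astype(float)
    return 0.5 * (np.tanh((z - z1) / width) - np.tanh((z - z2) / width))


def make_two_phase(spec: TwoPhaseSpec, seed: int = 0) -> SystemState:
    """Particle realization of a two-phase slab with Maxwell velocities.

    Positions are drawn by rejection against the smoothed density profile;
    species are Bernoulli draws from the smoothed purity profile; chains are
    assigned as contiguous blocks of ``chain_length`` labels within each
    species (topology-only).
    """
    rng = np.random.default_rng(seed)
    box = SimulationBox(np.asarray(spec.box, dtype=np.float64))
    Lx, Ly, Lz = box.lengths
    z1, z2 = spec.z12
    rho_h, rho_c = spec.rho_hot_phase, spec.rho_cold_phase
    rho_max = max(rho_h, rho_c)
    if rho_max <= 0:
        raise ValueError("at least one phase must contain particles")

    v_hot = Lx * Ly * (z2 - z1)
    n_total = int(round(rho_c * (box.volume - v_hot) + rho_h * v_hot))

    def corrugation_shift(x, y):
        d = np.zeros_like(x)
        for (n, m, amp) in spec.corrugation:
            d = d + amp * np.cos(2.0 * np.pi * (n * x / Lx + m * y / Ly))
        return d

    pos = np.empty((0, 3))
    while pos.shape[0] < n_total:
        batch = max(int(1.5 * (n_total - pos.shape[0]) / max(min(rho_h, rho_c)
                    / rho_max, 0.05)), 1000)
        cand = rng.random((batch, 3)) * box.lengths
        d = corrugation_shift(cand[:, 0], cand[:, 1])
        s = _phase_indicator(cand[:, 2] - d, z1, z2, spec.width)
        rho_local = rho_c + (rho_h - rho_c) * s
        accept = rng.random(batch) * rho_max < rho_local
        pos = np.vstack([pos, cand[accept]])
    pos = pos[:n_total]

    d = corrugation_shift(pos[:, 0], pos[:, 1])
    s = _phase_indicator(pos[:, 2] - d, z1, z2, spec.width)
    p_hot = (1.0 - spec.purity_cold_phase) + (
        spec.purity_hot_phase - (1.0 - spec.purity_cold_phase)) * s
    species = (rng.random(n_total) < p_hot).astype(np.int8)

    if spec.enforce_equal_composition:
        frac = species.mean()
        if abs(frac - 0.5) > 0.05:
            raise ValueError(
                f"phase purities/densities give hot fraction {frac:.3f}, "
                "inconsistent with the requested 50/50 composition")

    vel = rng.standard_normal((n_total, 3))
    vel[species == HOT] *= math.sqrt(spec.T_hot_species)
    vel[species == COLD] *= math.sqrt(spec.T_cold_species)

    chain_id = np.empty(n_total, dtype=np.int32)
    next_chain = 0
    for code in (HOT, COLD):
        idx = np.nonzero(species == code)[0]
        n_chains = math.ceil(idx.size / spec.chain_length)
        labels = next_chain + np.arange(idx.size) // spec.chain_length
        chain_id[idx] = labels
        next_chain += n_chains
    return SystemState(positions=box.wrap(pos), velocities=vel,
                       species=species, chain_id=chain_id, box=box, time=0.0)


def make_two_phase_trajectory(spec: TwoPhaseSpec, n_snapshots: int,
                              seed: int = 0) -> "Trajectory":
    """Snapshot ensemble of one two-phase system with fixed labels.

    The species and chain labels come from the first realization; later
    snapshots redraw positions from the species-conditional spatial law
    (and fresh Maxwell velocities), emulating independent steady-state
    configurations of one labeled system.
    """
    from .md import Trajectory

    rng = np.random.default_rng(seed)
    first = make_two_phase(spec, seed=int(rng.integers(2 ** 31)))
    states = [first]
    box = first.box
    Lx, Ly, Lz = box.lengths
    z1, z2 = spec.z12
    rho_h, rho_c = spec.rho_hot_phase, spec.rho_cold_phase

    def corrugation_shift(x, y):
        d = np.zeros_like(x)
        for (n, m, amp) in spec.corrugation:
            d = d + amp * np.cos(2.0 * np.pi * (n * x / Lx + m * y / Ly))
        return d

    def conditional_positions(code, count):
        # density of particles of this species: rho(z) * p_species(z)
        out = np.empty((0, 3))
        while out.shape[0] < count:
            cand = rng.random((max(4 * count, 1000), 3)) * box.lengths
            d = corrugation_shift(cand[:, 0], cand[:, 1])
            s = _phase_indicator(cand[:, 2] - d, z1, z2, spec.width)
            rho_local = rho_c + (rho_h - rho_c) * s
            p_hot = (1.0 - spec.purity_cold_phase) + (
                spec.purity_hot_phase - (1.0 - spec.purity_cold_phase)) * s
            weight = rho_local * (p_hot if code == HOT else 1.0 - p_hot)
            wmax = weight.max()
            if wmax <= 0:
                raise ValueError("species absent from every phase")
            accept = rng.random(cand.shape[0]) * wmax < weight
            out = np.vstack([out, cand[accept]])
        return out[:count]

    n_hot = int((first.species == HOT).sum())
    n_cold = first.n_particles - n_hot
    for t in range(1, n_snapshots):
        pos = np.empty((first.n_particles, 3))
        pos[first.species == HOT] = conditional_positions(HOT, n_hot)
        pos[first.species == COLD] = conditional_positions(COLD, n_cold)
        vel = rng.standard_normal((first.n_particles, 3))
        vel[first.species == HOT] *= math.sqrt(spec.T_hot_species)
        vel[first.species == COLD] *= math.sqrt(spec.T_cold_species)
        states.append(SystemState(positions=pos, velocities=vel,
                                  species=first.species,
                                  chain_id=first.chain_id, box=box,
                                  time=float(t)))
    return Trajectory.from_states(states)


def make_height_ensemble(spec: SpectrumSpec) -> list[HeightField]:
    """Independent Gaussian capillary height fields with a q^-2 spectrum.

    Each non-Nyquist unique mode carries cosine and sine amplitudes with
    Var(A) = Var(B) = 2/(gamma beta L^2 q^2); Nyquist rows are left empty.
    """
    rng = np.random.default_rng(spec.seed)
    nB, L = spec.nB, spec.L
    freqs = np.fft.fftfreq(nB, d=1.0 / nB).astype(np.int64)
    nyq = -(nB // 2)
    modes = []
    for a in range(nB):
        for b in range(nB):
            n, m = int(freqs[a]), int(freqs[b])
            if (n, m) == (0, 0) or n == nyq or m == nyq:
                continue
            if m > 0 or (m == 0 and n > 0):
                q = 2.0 * math.pi * math.hypot(n, m) / L
                modes.append((a, b, n, m, q))
    fields = []
    for t in range(spec.n_snapshots):
        H = np.zeros((nB, nB), dtype=complex)
        for (a, b, n, m, q) in modes:
            std = math.sqrt(2.0 / (spec.gamma_beta * L ** 2 * q ** 2))
            A = rng.normal(0.0, std)
            B = rng.normal(0.0, std)
            # A = 2 Re H, B = -2 Im H for the unique representative
            H[a, b] = 0.5 * (A - 1j * B)
            H[-a % nB, -b % nB] = 0.5 * (A + 1j * B)
        h = np.real(np.fft.ifft2(H * nB ** 2))
        fields.append(HeightField(h, L, "lower", time=float(t)))
    return fields


def make_ar1_series(tau_c: float, spacing: float, length: int,
                    seed: int = 0) -> np.ndarray:
    """Stationary unit-variance AR(1) series with autocorrelation exp(-t/tau_c)."""
    if tau_c <= 0:
        raise ValueError("correlation time must be positive")
    rng = np.random.default_rng(seed)
    phi = math.exp(-spacing / tau_c)
    x = np.empty(length)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(length - 1) * math.sqrt(1.0 - phi ** 2)
    for t in range(1, length):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def make_drho_curve(chi: np.ndarray, amplitude: float = DRHO_AMPLITUDE,
                    chi_star: float = DRHO_CHI_STAR, beta: float = DRHO_BETA,
                    noise: float = DRHO_NOISE, seed: int = 0) -> CriticalCurve:
    """Binodal density-difference data from the power law plus Gaussian noise."""
    chi = np.asarray(chi, dtype=np.float64)
    if np.any(chi <= chi_star):
        raise ValueError("chi grid must lie above chi*")
    rng = np.random.default_rng(seed)
    clean = amplitude * (chi - chi_star) ** beta
    values = clean + rng.normal(0.0, noise, size=chi.shape) if noise > 0 else clean
    errors = np.full(chi.shape, noise) if noise > 0 else None
    return CriticalCurve(chi=chi, values=values, errors=errors,
                         name="delta_rho")


def make_entropy_curve(chi: np.ndarray, chi_star: float = ENTROPY_CHI_STAR,
                       amplitude: float = 1.0, noise: float = 0.0,
                       seed: int = 0) -> CriticalCurve:
    """Quadratic-growth-to-plateau entropy-production curve.

    S(chi) = a chi^2 below chi* and the constant a chi*^2 above, with
    optional multiplicative Gaussian noise.
    """
    chi = np.asarray(chi, dtype=np.float64)
    clean = amplitude * np.minimum(chi, chi_star) ** 2
    if noise > 0:
        rng = np.random.default_rng(seed)
        values = clean * (1.0 + rng.normal(0.0, noise, size=chi.shape))
    else:
        values = clean
    return CriticalCurve(chi=chi, values=values, name="entropy_production")


def make_cumulant_family(chi: np.ndarray, ns: tuple[int, ...] = (4, 6, 8),
                         chi_star: float = 0.46,
                         level: float = CUMULANT_LEVEL,
                         noise: float = 0.0, seed: int = 0
                         ) -> list[CriticalCurve]:
    """Cumulant curves decreasing from 3 (Gaussian) to 1 (two-state).

    All curves pass through (chi*, level); curve steepness grows with n, so
    every pair crosses exactly at chi* in the noiseless limit.
    """
    chi = np.asarray(chi, dtype=np.float64)
    rng = np.random.default_rng(seed)
    curves = []
    for i, n in enumerate(ns):
        w = 0.4 / (1.0 + 0.5 * i)
        vals = level - (3.0 - level) * np.tanh((chi - chi_star) / w)
        vals = np.clip(vals, 1.0, 3.0)
        if noise > 0:
            vals = vals + rng.normal(0.0, noise, size=chi.shape)
        curves.append(CriticalCurve(chi=chi, values=vals,
                                    name=f"cumulant_n{n}"))
    return curves


def make_critical_curves(chi: np.ndarray, seed: int = 0,
                         noise_drho: float = DRHO_NOISE,
                         noise_entropy: float = 0.05,
                         ns: tuple[int, ...] = (4, 6, 8)) -> dict:
    """Bundle of critical-curve fixtures with their ground-truth parameters."""
    chi = np.asarray(chi, dtype=np.float64)
    above = chi[chi > DRHO_CHI_STAR + 1e-9]
    return {
        "delta_rho": make_drho_curve(above, noise=noise_drho, seed=seed),
        "entropy": make_entropy_curve(chi, noise=noise_entropy, seed=seed + 1),
        "cumulants": make_cumulant_family(chi, ns=ns, seed=seed + 2),
        "truth": {
            "drho": {"amplitude": DRHO_AMPLITUDE, "chi_star": DRHO_CHI_STAR,
                     "beta": DRHO_BETA},
            "entropy_chi_star": ENTROPY_CHI_STAR,
            "cumulant": {"chi_star": 0.46, "level": CUMULANT_LEVEL},
        },
    }
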