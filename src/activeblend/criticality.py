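"""Critical-asymmetry estimators and phase diagrams.

Three independent routes to the critical temperature asymmetry chi* of the
two-temperature blend: the growth-to-plateau crossover of the entropy
production, crossings of fourth-order (Binder-type) cumulants of sub-box
density fluctuations, and power-law fits Delta-rho = A (chi - chi*)^beta'
to binodal density differences.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .md import COLD, HOT, Trajectory
from .profiles import SlabProfile

logger = logging.getLogger("activeblend.criticality")


class NoCrossoverError(RuntimeError):
    """Monotone data with no plateau: the crossover point is undefined."""


class NoCrossingError(RuntimeError):
    """No cumulant curve pair changes sign: no crossing estimate."""


class PlateauError(RuntimeError):
    """Profile has no identifiable two-phase plateau structure."""


def mean_field_cumulant() -> float:
    """Mean-field reference crossing level [Gamma(1/4)]^4 / (8 pi^2) ~ 2.188."""
    return float(special.gamma(0.25) ** 4 / (8.0 * math.pi ** 2))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CriticalCurve:
    """An observable sampled on a strictly increasing chi grid."""

    chi: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    name: str = ""
    system_size: int | None = None

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=np.float64)
            if self.errors.shape != self.chi.shape:
                raise ValueError("errors must match chi grid")
        if self.chi.ndim != 1 or self.chi.shape != self.values.shape:
            raise ValueError("chi and values must be 1-D of equal length")
        if np.any(np.diff(self.chi) <= 0):
            raise ValueError("chi grid must be strictly increasing")


@dataclass
class CrossoverFit:
    chi_star: float
    uncertainty: float
    amplitude: float  # low-branch quadratic coefficient a in a*chi^2
    plateau: float  # high-branch constant
    n_windows: int


@dataclass
class CumulantConfig:
    ns: tuple[int, ...]
    rho_bar: float | None = None  # default: global species density

    def __post_init__(self):
        if any(n < 2 for n in self.ns):
            raise ValueError("sub-box linear counts must be >= 2")


@dataclass
class CrossingEstimate:
    chi_star: float
    spread: float
    level: float
    crossings: list[float]


@dataclass
class PowerLawFit:
    amplitude: float
    chi_star: float
    beta: float
    covariance: np.ndarray  # 3x3 in (ln A, chi*, beta') order, fixed rows zero
    fixed: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Entropy production
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntropyProduction:
    """Steady-state entropy production per hot particle.

    ``per_3zeta`` is Theff/Th + Tceff/Tc - 2 (the reservoir heat-flux sum in
    units of 3 zeta); ``rate`` multiplies back the 3 zeta.
    """

    per_3zeta: float
    rate: float


def entropy_production(theff: float, tceff: float, thermo) -> EntropyProduction:
    """Entropy production from measured effective temperatures.

    Zero iff both effective temperatures equal their reservoirs; positive
    whenever heat flows down-gradient through the system.
    """
    if thermo.Th <= 0 or thermo.Tc <= 0:
        raise ValueError("reservoir temperatures must be positive")
    per = theff / thermo.Th + tceff / thermo.Tc - 2.0
    return EntropyProduction(per_3zeta=per, rate=3.0 * thermo.zeta * per)


# ---------------------------------------------------------------------------
# Crossover estimator
# ---------------------------------------------------------------------------

def crossover_chi_star(curve: CriticalCurve) -> CrossoverFit:
    """chi* as the crossover between a*chi^2 growth and a high-chi plateau.

    The split between the two fit windows is scanned over all interior
    positions leaving at least three points per branch; the quadratic branch
    is constrained through the origin.  Windows whose combined squared error
    is within a factor two of the best split are averaged; their spread is
    the quoted uncertainty.  Strictly monotone data (a pure quadratic fits as
    well as any split) raise :class:`NoCrossoverError`.
    """
    x, y = curve.chi, curve.values
    n = x.size
    if n < 6:
        raise ValueError("need at least three points per branch")
    candidates = []
    for k in range(3, n - 2):
        xl, yl = x[:k], y[:k]
        xh, yh = x[k:], y[k:]
        a = float(np.sum(yl * xl ** 2) / np.sum(xl ** 4))
        c = float(np.mean(yh))
        if a <= 0 or c <= 0:
            continue
        sse = float(np.sum((yl - a * xl ** 2) ** 2) + np.sum((yh - c) ** 2))
        chi_star = math.sqrt(c / a)
        if x[0] <= chi_star <= x[-1]:
            candidates.append((sse, chi_star, a, c))
    if not candidates:
        raise NoCrossoverError("no admissible crossover window")
    sse_min = min(c[0] for c in candidates)
    # guard: if one quadratic explains everything, there is no plateau
    a_all = float(np.sum(y * x ** 2) / np.sum(x ** 4))
    sse_quad = float(np.sum((y - a_all * x ** 2) ** 2))
    scale = 1e-12 * float(np.sum(y ** 2))
    if sse_quad <= sse_min + scale:
        raise NoCrossoverError("data consistent with a single quadratic; "
                               "no plateau regime detected")
    admissible = [c for c in candidates if c[0] <= 2.0 * sse_min + scale]
    chis = np.array([c[1] for c in admissible])
    return CrossoverFit(
        chi_star=float(chis.mean()),
        uncertainty=float(chis.std(ddof=0)),
        amplitude=float(np.mean([c[2] for c in admissible])),
        plateau=float(np.mean([c[3] for c in admissible])),
        n_windows=len(admissible),
    )


# ---------------------------------------------------------------------------
# Sub-box cumulants
# ---------------------------------------------------------------------------

def _subbox_densities(traj: Trajectory, n: int, mask: np.ndarray) -> np.ndarray:
    """Per-snapshot densities of masked particles in n^3 equal sub-boxes.

    Wrapped coordinates are used directly (no alignment): sub-box statistics
    must not depend on where the interface happens to sit.
    """
    L = traj.box.lengths
    vol = traj.box.volume / n ** 3
    T = len(traj)
    out = np.empty((T, n ** 3))
    for t in range(T):
        p = traj.positions[t][mask]
        ix = np.minimum((p[:, 0] / L[0] * n).astype(np.int64), n - 1)
        iy = np.minimum((p[:, 1] / L[1] * n).astype(np.int64), n - 1)
        iz = np.minimum((p[:, 2] / L[2] * n).astype(np.int64), n - 1)
        flat = (ix * n + iy) * n + iz
        out[t] = np.bincount(flat, minlength=n ** 3) / vol
    return out


def fourth_order_cumulant(traj: Trajectory, cfg: CumulantConfig,
                          species: str = "hot") -> dict[int, float]:
    """Fourth-order sub-box density cumulant Un for each requested n.

    Un = <m4> / <m2>^2 with m4, m2 the per-snapshot fourth and second central
    moments of the n^3 sub-box densities about ``rho_bar`` (default: the
    global species density).  Gaussian fluctuations give 3, a symmetric
    two-state distribution gives 1.
    """
    code = {"hot": HOT, "cold": COLD}[species]
    mask = traj.species == code
    if not mask.any():
        raise ValueError(f"no {species} particles")
    rho_bar = cfg.rho_bar
    if rho_bar is None:
        rho_bar = float(mask.sum() / traj.box.volume)
    result = {}
    for n in cfg.ns:
        rho = _subbox_densities(traj, n, mask)
        dev = rho - rho_bar
        m2 = np.mean(dev ** 2, axis=1)
        m4 = np.mean(dev ** 4, axis=1)
        denom = float(np.mean(m2)) ** 2
        if denom == 0:
            raise ZeroDivisionError("all sub-boxes at the reference density")
        result[n] = float(np.mean(m4)) / denom
    return result


def cumulant_crossings(curves: list[CriticalCurve]) -> CrossingEstimate:
    """chi* from pairwise crossings of cumulant curves at different n.

    Crossings are located by linear interpolation between adjacent chi
    samples; pairs whose difference never changes sign are skipped.  The mean
    crossing is the estimate and the standard deviation its error.
    """
    if len(curves) < 2:
        raise ValueError("need at least two cumulant curves")
    grid = curves[0].chi
    for c in curves[1:]:
        if c.chi.shape != grid.shape or not np.allclose(c.chi, grid):
            raise ValueError("cumulant curves must share one chi grid")
    crossings, levels = [], []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            d = curves[i].values - curves[j].values
            sign = np.sign(d)
            for k in range(d.size - 1):
                if sign[k] == 0:
                    crossings.append(float(grid[k]))
                    levels.append(float(curves[i].values[k]))
                elif sign[k] * sign[k + 1] < 0:
                    frac = d[k] / (d[k] - d[k + 1])
                    xc = grid[k] + frac * (grid[k + 1] - grid[k])
                    uc = curves[i].values[k] + frac * (
                        curves[i].values[k + 1] - curves[i].values[k])
                    crossings.append(float(xc))
                    levels.append(float(uc))
    if not crossings:
        raise NoCrossingError("no cumulant curve pair crosses")
    arr = np.asarray(crossings)
    return CrossingEstimate(chi_star=float(arr.mean()),
                            spread=float(arr.std(ddof=0)),
                            level=float(np.mean(levels)),
                            crossings=crossings)


# ---------------------------------------------------------------------------
# Binodals
# ---------------------------------------------------------------------------

def plateau_values(profile: SlabProfile, width: float,
                   label: str = "") -> tuple[float, float, float, float]:
    """(dense, dense_sd, dilute, dilute_sd) plateau statistics of a profile.

    The two interfaces are the mid-level crossings of the profile; plateau
    slabs lie farther than 1.5x the interfacial ``width`` from both.  For
    crossing detection the profile is smoothed with a circular three-slab
    moving average (interfaces are wider than one slab; raw values are kept
    for the plateau statistics).  Raises :class:`PlateauError` for mixed
    profiles (not exactly two crossings) or when a branch retains fewer
    than two plateau slabs.
    """
    z, v = profile.centers, profile.values
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise PlateauError(f"profile too sparse for plateaus {label}")
    vs = v.copy()
    if np.all(finite) and v.size >= 5:
        vs = (np.roll(v, 1) + v + np.roll(v, -1)) / 3.0
    mid = 0.5 * (np.nanmax(vs) + np.nanmin(vs))
    d = vs - mid
    nz = z.size
    dz_slab = z[1] - z[0]
    L = float(z[-1] + dz_slab / 2.0)  # centers start at dz/2, so this is the length
    crossings = []
    for k in range(nz):  # periodic: include the wrap-around segment
        k2 = (k + 1) % nz
        if not (np.isfinite(d[k]) and np.isfinite(d[k2])):
            continue
        if d[k] == 0 or d[k] * d[k2] < 0:
            frac = 0.0 if d[k] == 0 else d[k] / (d[k] - d[k2])
            crossings.append(float((z[k] + frac * dz_slab) % L))
    if len(crossings) != 2:
        raise PlateauError(
            f"expected two mid-level crossings, found {len(crossings)} {label}")
    z1, z2 = crossings
    dist = np.minimum(np.abs(z - z1), L - np.abs(z - z1))
    dist = np.minimum(dist, np.minimum(np.abs(z - z2), L - np.abs(z - z2)))
    plateau = dist > 1.5 * width
    inner = (z > min(z1, z2)) & (z < max(z1, z2))
    branch_a = plateau & inner & finite
    branch_b = plateau & ~inner & finite
    if branch_a.sum() < 2 or branch_b.sum() < 2:
        raise PlateauError(f"no plateau region (system too small) {label}")
    mean_a, sd_a = float(v[branch_a].mean()), float(v[branch_a].std(ddof=1))
    mean_b, sd_b = float(v[branch_b].mean()), float(v[branch_b].std(ddof=1))
    if mean_a >= mean_b:
        return mean_a, sd_a, mean_b, sd_b
    return mean_b, sd_b, mean_a, sd_a


@dataclass
class BinodalEntry:
    chi: float
    profiles: dict[str, SlabProfile]  # e.g. density / phi_h / msv
    width: float
    Th: float | None = None


def binodal_from_profiles(entries: list[BinodalEntry]):
    """Phase-diagram table of plateau values per branch and observable."""
    import pandas as pd

    rows = []
    for e in sorted(entries, key=lambda e: e.chi):
        for obs, prof in e.profiles.items():
            label = f"(Th={e.Th})" if e.Th is not None else f"(chi={e.chi:.3g})"
            dense, dense_sd, dilute, dilute_sd = plateau_values(
                prof, e.width, label)
            rows.append({
                "chi": e.chi, "Th": e.Th, "observable": obs,
                "dense": dense, "dense_sd": dense_sd,
                "dilute": dilute, "dilute_sd": dilute_sd,
                "difference": dense - dilute,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power-law critical fit
# ---------------------------------------------------------------------------

def power_law_fit(chi: np.ndarray, values: np.ndarray,
                  errors: np.ndarray | None = None,
                  fix: dict[str, float] | None = None) -> PowerLawFit:
    """Weighted log-log fit of Delta-rho = A (chi - chi*)^beta'.

    Any subset of {"A", "chi_star", "beta"} may be fixed via ``fix``.  When
    chi* is free it is parametrized logistically so that 0 < chi* < chi_min:
    the asymmetry parameter is nonnegative and every data point must lie in
    the power law's support.  (Without the lower bound the three-parameter
    model has a runaway ridge chi* -> -inf with growing beta'.)  Nonpositive
    observable values (possible under additive noise near the critical
    point) are dropped before taking logs.  Requires at least three degrees
    of freedom beyond the free parameters.
    """
    fix = dict(fix or {})
    unknown = set(fix) - {"A", "chi_star", "beta"}
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
    chi = np.asarray(chi, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    keep = values > 0
    if errors is not None:
        errors = np.asarray(errors, dtype=np.float64)
        keep &= errors > 0
    if not keep.all():
        logger.info("power_law_fit: dropping %d nonpositive points",
                    int((~keep).sum()))
    x, y = chi[keep], values[keep]
    w = np.ones_like(y) if errors is None else y / errors[keep]  # 1/sigma_ln
    free = [p for p in ("A", "chi_star", "beta") if p not in fix]
    if x.size - len(free) < 3:
        raise ValueError("need at least three degrees of freedom")
    xmin = float(x.min())
    if "chi_star" in fix and fix["chi_star"] >= xmin:
        raise ValueError("fixed chi* must lie below every chi sample")

    lny = np.log(y)

    def unpack(p):
        i = 0
        if "A" in fix:
            lnA = math.log(fix["A"])
        else:
            lnA = p[i]; i += 1
        if "chi_star" in fix:
            cs = fix["chi_star"]
        else:
            cs = xmin / (1.0 + math.exp(-p[i])); i += 1
        beta = fix.get("beta", None)
        if beta is None:
            beta = p[i]
        return lnA, cs, beta

    def residuals(p):
        lnA, cs, beta = unpack(p)
        return w * (lnA + beta * np.log(x - cs) - lny)

    # initial guess: linear regression at a support-safe chi*
    cs0 = fix.get("chi_star", 0.7 * xmin)
    X = np.log(x - cs0)
    beta0, lnA0 = np.polyfit(X, lny, 1)
    p0 = []
    if "A" not in fix:
        p0.append(lnA0)
    if "chi_star" not in fix:
        p0.append(math.log(cs0 / (xmin - cs0)))
    if "beta" not in fix:
        p0.append(beta0)
    sol = optimize.least_squares(residuals, np.asarray(p0), method="lm",
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    lnA, cs, beta = unpack(sol.x)

    # covariance in (lnA, chi*, beta) via the Jacobian and the chain rule
    cov_full = np.zeros((3, 3))
    dof = x.size - len(free)
    if sol.jac is not None and len(free) > 0:
        jtj = sol.jac.T @ sol.jac
        cov_p = np.linalg.pinv(jtj)  # pseudo-inverse: boundary fits can
        # flatten the chi* direction and make J'J numerically singular
        s2 = float(np.sum(sol.fun ** 2) / max(dof, 1))
        cov_p = cov_p * s2
        # chain rule for the logistic map u -> chi*
        scale = []
        for p in free:
            scale.append(cs * (1.0 - cs / xmin) if p == "chi_star" else 1.0)
        D = np.diag(scale)
        cov_p = D @ cov_p @ D.T
        idx = {"A": 0, "chi_star": 1, "beta": 2}
        for a, pa in enumerate(free):
            for b, pb in enumerate(free):
                cov_full[idx[pa], idx[pb]] = cov_p[a, b]
    return PowerLawFit(amplitude=math.exp(lnA), chi_star=cs, beta=beta,
                       covariance=cov_full, fixed=tuple(sorted(fix)))
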