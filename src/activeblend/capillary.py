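"""Capillary-wave analysis of phase-boundary fluctuations.

Interface heights are extracted on nB x nB block grids from the zero
crossing of the hot-cold density difference, Fourier-decomposed into
cosine/sine amplitudes (A, B) with C^2 = (A^2 + B^2)/2, and averaged into a
spectrum <C^2>(q).  An equilibrium-like spectrum L^2 <C^2> = 2/(gamma beta
q^2) defines the interfacial stiffness gamma*beta, which is also recovered
from the growth of the apparent squared interface width with block
resolution, w^2 = ln(nB/c) / (2 pi gamma beta).

Mode bookkeeping: modes are enumerated over unique half-plane
representatives (one entry per +-k pair), so that the spatial variance of a
height field equals the sum of C^2 over modes (exactly, per snapshot).
Self-conjugate Nyquist modes carry no sine partner and are flagged; they are
excluded from spectra and generators.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .md import HOT, SystemState, Trajectory

logger = logging.getLogger("activeblend.capillary")


class InterfaceExtractionError(RuntimeError):
    """No usable interface heights (mixed state or all blocks rejected)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class HeightField:
    """Interface heights h(x_i, y_j) on an nB x nB block grid."""

    heights: np.ndarray  # (nB, nB)
    length: float  # lateral box edge L (x == y)
    interface: str  # "lower" | "upper"
    time: float = 0.0

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2 or self.heights.shape[0] != self.heights.shape[1]:
            raise ValueError("heights must be a square grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height field contains missing blocks")

    @property
    def nB(self) -> int:
        return self.heights.shape[0]


@dataclass
class ModeAmplitudes:
    """Real Fourier amplitudes of one height field over unique modes."""

    n_idx: np.ndarray
    m_idx: np.ndarray
    q: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C2: np.ndarray
    nyquist: np.ndarray  # any Nyquist component: kept for Parseval only


@dataclass
class CapillarySpectrum:
    """Ensemble-averaged <C^2> binned by wavevector magnitude."""

    q: np.ndarray
    c2: np.ndarray
    stderr: np.ndarray
    nB: int
    length: float
    n_snapshots: int
    modes_per_bin: np.ndarray


@dataclass
class StiffnessEstimate:
    gamma_beta: float
    uncertainty: float
    method: str  # "spectrum" | "width"
    nB: tuple[int, ...]
    excluded_modes: tuple = ()
    physical: bool = True  # False flags nonpositive fits (unseparated input)


@dataclass
class WidthScaling:
    nB: np.ndarray
    w2: np.ndarray
    w2_err: np.ndarray
    gamma_beta: float
    gamma_beta_err: float
    c: float
    fit_range: tuple[int, int]


@dataclass
class ModeAutocorrelation:
    lags: np.ndarray
    c: np.ndarray
    tau_c: float


# ---------------------------------------------------------------------------
# Interface heights
# ---------------------------------------------------------------------------

def interface_heights(state: SystemState, nB: int,
                      n_slabs: int | None = None
                      ) -> tuple[HeightField, HeightField]:
    """Block-resolved heights of the two interfaces of an aligned snapshot.

    Per block, the interface height is the linearly interpolated zero
    crossing of the hot-minus-cold slab density difference m(z), taken
    nearest the corresponding whole-box interface position.  The two
    interfaces are resolved by splitting the box at the hot-phase center
    (z = Lz/2 after alignment).  Any block without a sign change rejects the
    snapshot for this nB (logged).
    """
    L = state.box.lengths
    if not math.isclose(L[0], L[1], rel_tol=1e-9):
        raise ValueError("block analysis requires a square x-y cross-section")
    Lxy, Lz = float(L[0]), float(L[2])
    nz = n_slabs or max(int(round(Lz)), 8)
    dz = Lz / nz
    pos = state.positions
    hot = state.species == HOT
    # mixed-state guard: a separated, aligned snapshot has a strong first
    # circular harmonic in the hot-monomer z-distribution
    amp = abs(np.mean(np.exp(2j * np.pi * pos[hot, 2] / Lz)))
    if amp < 0.2:
        raise InterfaceExtractionError(
            f"no two-phase structure along z (harmonic amplitude {amp:.3f})")
    sgn = np.where(hot, 1.0, -1.0)

    bx = np.minimum((pos[:, 0] / Lxy * nB).astype(np.int64), nB - 1)
    by = np.minimum((pos[:, 1] / Lxy * nB).astype(np.int64), nB - 1)
    bz = np.minimum((pos[:, 2] / dz).astype(np.int64), nz - 1)
    flat = (bx * nB + by) * nz + bz
    m = np.bincount(flat, weights=sgn, minlength=nB * nB * nz)
    m = m.reshape(nB, nB, nz)
    m_global = m.sum(axis=(0, 1))
    zc = (np.arange(nz) + 0.5) * dz

    halves = [(slice(0, nz // 2), "lower"), (slice(nz // 2, nz), "upper")]
    global_pos = {}
    for sl, name in halves:
        g = _nearest_crossing(m_global[sl], zc[sl], target=None)
        if g is None:
            raise InterfaceExtractionError(
                f"no {name} interface in the global profile (mixed state?)")
        global_pos[name] = g

    fields = []
    for sl, name in halves:
        h = np.full((nB, nB), np.nan)
        rejected = 0
        for i in range(nB):
            for j in range(nB):
                zcross = _nearest_crossing(m[i, j, sl], zc[sl],
                                           target=global_pos[name])
                if zcross is None:
                    rejected += 1
                else:
                    h[i, j] = zcross
        if rejected:
            logger.info("nB=%d: %d/%d blocks without sign change at t=%.0f; "
                        "snapshot rejected", nB, rejected, nB * nB, state.time)
            raise InterfaceExtractionError(
                f"{rejected} blocks lack a density-difference crossing")
        fields.append(HeightField(h, Lxy, name, state.time))
    return fields[0], fields[1]


def _nearest_crossing(m: np.ndarray, zc: np.ndarray,
                      target: float | None) -> float | None:
    """Linearly interpolated zero crossing of m(z), nearest `target`."""
    crossings = []
    for k in range(m.size - 1):
        a, b = m[k], m[k + 1]
        if a == 0.0 and b == 0.0:
            continue
        if a == 0.0:
            crossings.append(float(zc[k]))
        elif a * b < 0:
            frac = a / (a - b)
            crossings.append(float(zc[k] + frac * (zc[k + 1] - zc[k])))
    if m[-1] == 0.0 and m.size > 1 and m[-2] != 0.0:
        crossings.append(float(zc[-1]))
    if not crossings:
        return None
    if target is None:
        # whole-box profile: pick the crossing with the steepest slope around
        mid = zc[0] + 0.5 * (zc[-1] - zc[0])
        return min(crossings, key=lambda z: abs(z - mid))
    return min(crossings, key=lambda z: abs(z - target))


def trajectory_heights(traj: Trajectory, nB: int,
                       n_slabs: int | None = None,
                       spacing: float | None = None) -> list[HeightField]:
    """All usable height fields (both interfaces) of an aligned trajectory.

    ``spacing`` subsamples snapshots to at least that separation in time,
    for decorrelated spectra.
    """
    fields = []
    last_t = -math.inf
    for t in range(len(traj)):
        time = float(traj.times[t])
        if spacing is not None and time - last_t < spacing * (1 - 1e-9):
            continue
        try:
            lo, up = interface_heights(traj.snapshot(t), nB, n_slabs)
        except InterfaceExtractionError:
            continue
        fields.extend([lo, up])
        last_t = time
    return fields


# ---------------------------------------------------------------------------
# Fourier amplitudes and spectra
# ---------------------------------------------------------------------------

def fourier_amplitudes(hf: HeightField) -> ModeAmplitudes:
    """Cosine/sine amplitudes over unique (half-plane) modes, mean removed.

    Parseval holds exactly: sum of C^2 over all returned modes equals the
    spatial variance of the height grid.
    """
    nB = hf.nB
    H = np.fft.fft2(hf.heights - hf.heights.mean()) / nB ** 2
    freqs = np.fft.fftfreq(nB, d=1.0 / nB).astype(np.int64)  # signed indices
    # blocks represent averages around their centers (i + 1/2) L/nB; rotate
    # the FFT phases so a center-sampled cosine lands purely in A
    phase = np.exp(-1j * math.pi * (freqs[:, None] + freqs[None, :]) / nB)
    H = H * phase
    n_idx, m_idx, A, B, C2, selfc = [], [], [], [], [], []
    nyq = -(nB // 2)  # fftfreq labels the Nyquist index as negative
    for a in range(nB):
        for b in range(nB):
            n, m = int(freqs[a]), int(freqs[b])
            if n == 0 and m == 0:
                continue
            # unique representative of the +-k pair
            if not (m > 0 or (m == 0 and n > 0) or
                    (m == nyq and (n > 0 or n == 0 or n == nyq)) or
                    (n == nyq and m == 0)):
                continue
            is_nyquist = n == nyq or m == nyq
            is_self = (n in (0, nyq)) and (m in (0, nyq))
            h = H[a, b]
            if is_self:
                amp_a, amp_b = float(h.real), 0.0
                c2 = abs(h) ** 2
            else:
                amp_a, amp_b = 2.0 * h.real, -2.0 * h.imag
                c2 = 0.5 * (amp_a ** 2 + amp_b ** 2)
            n_idx.append(n)
            m_idx.append(m)
            A.append(amp_a)
            B.append(amp_b)
            C2.append(c2)
            selfc.append(is_nyquist)
    q = 2.0 * math.pi * np.hypot(n_idx, m_idx) / hf.length
    return ModeAmplitudes(np.asarray(n_idx), np.asarray(m_idx), q,
                          np.asarray(A), np.asarray(B), np.asarray(C2),
                          np.asarray(selfc, dtype=bool))


def spectrum_from_heights(fields: list[HeightField],
                          min_fields: int = 1) -> CapillarySpectrum:
    """Ensemble <C^2> binned by |q| over height fields of equal nB.

    Self-conjugate Nyquist modes are excluded.  Errors are standard errors
    over fields of the per-field mean within each |q| bin.
    """
    if not fields:
        raise ValueError("no height fields supplied")
    if len(fields) < min_fields:
        raise ValueError(f"fewer than {min_fields} usable height fields")
    nB, L = fields[0].nB, fields[0].length
    for f in fields:
        if f.nB != nB or not math.isclose(f.length, L):
            raise ValueError("height fields must share nB and box size")
    modes0 = fourier_amplitudes(fields[0])
    keep = ~modes0.nyquist
    q = modes0.q[keep]
    c2 = np.empty((len(fields), keep.sum()))
    c2[0] = modes0.C2[keep]
    for t, f in enumerate(fields[1:], start=1):
        c2[t] = fourier_amplitudes(f).C2[keep]
    qr = np.round(q, 9)
    q_bins = np.unique(qr)
    means = np.empty(q_bins.size)
    errs = np.empty(q_bins.size)
    nmodes = np.empty(q_bins.size, dtype=np.int64)
    for i, qb in enumerate(q_bins):
        cols = qr == qb
        per_field = c2[:, cols].mean(axis=1)
        means[i] = per_field.mean()
        errs[i] = (per_field.std(ddof=1) / math.sqrt(len(fields))
                   if len(fields) > 1 else np.nan)
        nmodes[i] = int(cols.sum())
    return CapillarySpectrum(q=q_bins, c2=means, stderr=errs, nB=nB,
                             length=L, n_snapshots=len(fields),
                             modes_per_bin=nmodes)


def spectrum_accumulate(traj: Trajectory, nB: int,
                        spacing: float | None = None,
                        n_slabs: int | None = None,
                        min_snapshots: int = 10) -> CapillarySpectrum:
    """Capillary spectrum of an aligned trajectory at block resolution nB.

    Snapshots are subsampled to ``spacing`` (decorrelation of the slowest
    mode); both interfaces enter as independent samples.  Fewer than
    ``min_snapshots`` usable snapshots is an error.
    """
    fields = trajectory_heights(traj, nB, n_slabs, spacing)
    if len(fields) < 2 * min_snapshots:
        raise ValueError(
            f"only {len(fields) // 2} usable snapshots (< {min_snapshots})")
    return spectrum_from_heights(fields)


def stiffness_from_spectrum(spectra, exclude_slowest: bool = False
                            ) -> StiffnessEstimate:
    """Interfacial stiffness gamma*beta from <C^2> = 2/(gamma beta L^2 q^2).

    A single weighted one-parameter fit of the prefactor; with several
    spectra (different nB) the estimate is their mean and the spread is the
    quoted uncertainty.  ``exclude_slowest`` drops the (0,1)/(1,0) bin to
    guard against correlated sampling of the slowest mode.
    """
    if isinstance(spectra, CapillarySpectrum):
        spectra = [spectra]
    estimates, variances = [], []
    for spec in spectra:
        q, y, err = spec.q, spec.c2, spec.stderr
        if exclude_slowest:
            keep = q > q.min()
            q, y, err = q[keep], y[keep], err[keep]
        if q.size < 5:
            raise ValueError("need at least five modes to fit the spectrum")
        x = 2.0 / (spec.length ** 2 * q ** 2)
        w = np.ones_like(y)
        if np.all(np.isfinite(err)) and np.all(err > 0):
            w = 1.0 / err ** 2
        s = float(np.sum(w * x * y) / np.sum(w * x * x))  # s = 1/(gamma beta)
        var_s = 1.0 / float(np.sum(w * x * x))
        estimates.append(1.0 / s if s != 0 else math.inf)
        variances.append(var_s / s ** 4 if s != 0 else math.inf)
    est = np.asarray(estimates)
    if len(est) == 1:
        gb, unc = float(est[0]), float(math.sqrt(variances[0]))
    else:
        gb, unc = float(est.mean()), float(est.std(ddof=1))
    physical = bool(gb > 0)
    if not physical:
        logger.warning("nonpositive fitted stiffness: sub-critical or "
                       "unseparated input")
    return StiffnessEstimate(
        gamma_beta=gb, uncertainty=unc, method="spectrum",
        nB=tuple(s.nB for s in spectra),
        excluded_modes=("slowest",) if exclude_slowest else (),
        physical=physical)


# ---------------------------------------------------------------------------
# Mode autocorrelation
# ---------------------------------------------------------------------------

def autocorrelation_time(series: np.ndarray, spacing: float,
                         threshold: float = 0.05) -> ModeAutocorrelation:
    """Exponential correlation time of a scalar series at uniform spacing.

    The normalized autocovariance c(t) (c(0) = 1 exactly) is fitted
    log-linearly over lags with c(t) > ``threshold``, stopping at the first
    nonpositive excursion.
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError("series too short")
    xm = x - x.mean()
    var = float(np.mean(xm ** 2))
    if var == 0:
        raise ValueError("zero-variance series")
    max_lag = n // 2
    c = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        c[k] = float(np.mean(xm[:n - k] * xm[k:])) / var
    lags = np.arange(max_lag + 1) * spacing
    # usable window: before the first excursion at or below the threshold
    stop = max_lag + 1
    for k in range(1, max_lag + 1):
        if c[k] <= threshold:
            stop = k
            break
    if stop < 2:
        # decorrelated already at one lag: tau below the sampling interval
        return ModeAutocorrelation(lags=lags, c=c, tau_c=float(spacing)
                                   if c[1] > 0 else 0.0)
    k_fit = np.arange(stop)
    slope = np.polyfit(lags[k_fit], np.log(c[k_fit]), 1)[0]
    tau = -1.0 / slope if slope < 0 else math.inf
    return ModeAutocorrelation(lags=lags, c=c, tau_c=float(tau))


def mode_amplitude_series(fields: list[HeightField],
                          mode: tuple[int, int] = (0, 1)) -> np.ndarray:
    """C_nm = sqrt((A^2+B^2)/2) of one mode across a height-field sequence."""
    out = np.empty(len(fields))
    for t, f in enumerate(fields):
        amps = fourier_amplitudes(f)
        sel = (amps.n_idx == mode[0]) & (amps.m_idx == mode[1])
        if not sel.any():
            # the unique representative may be the conjugate partner
            sel = (amps.n_idx == -mode[0]) & (amps.m_idx == -mode[1])
        if not sel.any():
            raise ValueError(f"mode {mode} not present at nB={f.nB}")
        out[t] = math.sqrt(float(amps.C2[sel][0]))
    return out


def mode_autocorrelation(traj: Trajectory, nB: int = 8,
                         mode: tuple[int, int] = (0, 1),
                         n_slabs: int | None = None) -> ModeAutocorrelation:
    """Autocorrelation time of the slowest capillary mode of a trajectory.

    The two interfaces are treated as independent series; the returned tau_c
    averages their fits.
    """
    if len(traj) < 8:
        raise ValueError("need a finely sampled trajectory")
    spacing = float(np.mean(np.diff(traj.times)))
    lower, upper = [], []
    for t in range(len(traj)):
        lo, up = interface_heights(traj.snapshot(t), nB, n_slabs)
        lower.append(lo)
        upper.append(up)
    acs = [autocorrelation_time(mode_amplitude_series(f, mode), spacing)
           for f in (lower, upper)]
    tau = float(np.mean([a.tau_c for a in acs]))
    return ModeAutocorrelation(lags=acs[0].lags, c=0.5 * (acs[0].c + acs[1].c),
                               tau_c=tau)


# ---------------------------------------------------------------------------
# Width scaling
# ---------------------------------------------------------------------------

def width_from_heights(fields: list[HeightField]) -> tuple[float, float]:
    """Mean and standard error of the squared apparent width w^2 = Var h."""
    w2 = np.array([f.heights.var() for f in fields])
    err = w2.std(ddof=1) / math.sqrt(w2.size) if w2.size > 1 else np.nan
    return float(w2.mean()), float(err)


def width_scaling_from_heights(per_nb: dict[int, list[HeightField]],
                               fit_range: tuple[int, int] = (5, 9)
                               ) -> WidthScaling:
    """Two-parameter fit w^2 = ln(nB/c)/(2 pi gamma beta) over a block range.

    ``per_nb`` maps block counts to height-field ensembles.  The default fit
    window nB in [5, 9] targets the log-linear regime; at least three nB
    values must fall inside it.
    """
    nbs = np.array(sorted(per_nb))
    w2 = np.empty(nbs.size)
    w2_err = np.empty(nbs.size)
    for i, nb in enumerate(nbs):
        w2[i], w2_err[i] = width_from_heights(per_nb[nb])
    sel = (nbs >= fit_range[0]) & (nbs <= fit_range[1])
    if sel.sum() < 3:
        raise ValueError(
            f"need at least three nB values in the fit range {fit_range}")
    x = np.log(nbs[sel].astype(np.float64))
    y = w2[sel]
    werr = w2_err[sel]
    if np.all(np.isfinite(werr)) and np.all(werr > 0):
        wts = 1.0 / werr ** 2
    else:
        wts = np.ones_like(y)
    W = np.sum(wts)
    xb = np.sum(wts * x) / W
    yb = np.sum(wts * y) / W
    sxx = np.sum(wts * (x - xb) ** 2)
    slope = float(np.sum(wts * (x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)
    if slope <= 0:
        raise ValueError("nonincreasing width with resolution: no capillary "
                         "broadening regime")
    var_slope = 1.0 / sxx
    gamma_beta = 1.0 / (2.0 * math.pi * slope)
    gb_err = var_slope ** 0.5 / (2.0 * math.pi * slope ** 2)
    c = math.exp(-intercept / slope)
    return WidthScaling(nB=nbs, w2=w2, w2_err=w2_err, gamma_beta=gamma_beta,
                        gamma_beta_err=float(gb_err), c=c,
                        fit_range=fit_range)


def width_vs_blocks(traj: Trajectory, nbs: list[int],
                    n_slabs: int | None = None,
                    spacing: float | None = None,
                    fit_range: tuple[int, int] = (5, 9)) -> WidthScaling:
    """Width-route stiffness from an aligned trajectory at several nB."""
    per_nb = {}
    for nb in nbs:
        fields = trajectory_heights(traj, nb, n_slabs, spacing)
        if not fields:
            raise InterfaceExtractionError(
                f"no usable snapshots at nB={nb}")
        per_nb[nb] = fields
    return width_scaling_from_heights(per_nb, fit_range)


# ---------------------------------------------------------------------------
# chi* from stiffness; width-chi scaling
# ---------------------------------------------------------------------------

def chi_star_from_stiffness(chi: np.ndarray, gamma_beta: np.ndarray,
                            errors: np.ndarray | None = None
                            ) -> tuple[float, float]:
    """chi* as the root of a weighted linear fit of gamma*beta vs sqrt(chi).

    Returns (chi*, uncertainty); the stiffness vanishes at the critical
    asymmetry, so chi* = (intercept root)^2.  A nonpositive slope (stiffness
    not growing with asymmetry) is unphysical and raises.
    """
    chi = np.asarray(chi, dtype=np.float64)
    gb = np.asarray(gamma_beta, dtype=np.float64)
    if chi.size < 2:
        raise ValueError("need at least two (chi, stiffness) points")
    s = np.sqrt(chi)
    if errors is not None and np.all(np.asarray(errors) > 0):
        wts = 1.0 / np.asarray(errors, dtype=np.float64) ** 2
    else:
        wts = np.ones_like(gb)
    W = np.sum(wts)
    xb = np.sum(wts * s) / W
    yb = np.sum(wts * gb) / W
    sxx = float(np.sum(wts * (s - xb) ** 2))
    slope = float(np.sum(wts * (s - xb) * (gb - yb)) / sxx)
    intercept = float(yb - slope * xb)
    if slope <= 0:
        raise ValueError("stiffness decreasing with sqrt(chi): unphysical")
    root = -intercept / slope
    chi_star = root ** 2
    # delta-method propagation through root = -b/p and chi* = root^2
    dof = max(chi.size - 2, 1)
    resid = gb - (slope * s + intercept)
    s2 = float(np.sum(wts * resid ** 2) / dof)
    var_slope = s2 / sxx
    var_inter = s2 * (1.0 / W + xb ** 2 / sxx)
    cov_si = -s2 * xb / sxx
    droot_dp = intercept / slope ** 2
    droot_db = -1.0 / slope
    var_root = (droot_dp ** 2 * var_slope + droot_db ** 2 * var_inter
                + 2.0 * droot_dp * droot_db * cov_si)
    unc = abs(2.0 * root) * math.sqrt(max(var_root, 0.0))
    return float(chi_star), float(unc)


def width_chi_scaling(entries: list[tuple[float, WidthScaling]]):
    """Tidy table of w * sqrt(chi) per nB, to exhibit the w ~ chi^(-1/2) law.

    Flatness of the product at large chi is a property to inspect, not a fit.
    """
    import pandas as pd

    rows = []
    for chi, ws in sorted(entries, key=lambda e: e[0]):
        for nb, w2 in zip(ws.nB, ws.w2):
            w = math.sqrt(w2) if w2 >= 0 else math.nan
            rows.append({"chi": chi, "nB": int(nb), "w": w,
                         "w_sqrt_chi": w * math.sqrt(chi)})
    return pd.DataFrame(rows)
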