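"""Trajectory motility statistics and fits.

Implements every measure used to compare model and experiment: per-step
instantaneous velocity, track directionality (tortuosity) chi = d_net / L,
mean squared displacement with overlapping windows and a 3/4-duration lag
cutoff, the drift-diffusion msd fit <r^2> = 4 D_eff dt + (v_eff dt)^2, the
anomalous-diffusion fit <r^2> = 4 D' t^alpha, the saturating distance-time
fit d(t) = d_max t^n / (T_half^n + t^n) whose cooperativity n separates
pulling (n > 1) from pushing (n <= 1), radial profiles, the lognormal
velocity fit and radial density.

All fits use scipy's bounded trust-region-reflective least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rwd import Trajectory

__all__ = [
    "MsdCurve", "MsdDriftFit", "MsdAnomalousFit", "DistanceTimeFit",
    "MotilitySummary", "downsample", "instantaneous_velocities",
    "directionality", "msd", "ensemble_msd", "fit_msd_drift",
    "fit_msd_anomalous", "fit_distance_time", "radial_profile",
    "fit_lognormal_velocity", "radial_density", "summarize_track",
]


class InsufficientDataError(ValueError):
    pass


class InvalidIntervalError(ValueError):
    pass


@dataclass
class MsdCurve:
    lags: np.ndarray      # s
    msd: np.ndarray       # um^2
    n_pairs: np.ndarray   # displacement pairs per lag


@dataclass
class MsdDriftFit:
    D_eff: float          # um^2/s
    v_eff: float          # um/s
    residual: float       # rms residual, um^2


@dataclass
class MsdAnomalousFit:
    D_prime: float        # um^2/s^alpha
    alpha: float          # in [0, 2]
    residual: float


@dataclass
class DistanceTimeFit:
    d_max: float          # um
    T_half: float         # s
    n: float              # cooperativity
    R2: float
    mode: str             # "pulling" iff n > 1, else "pushing"
    reliable: bool        # R^2 > 0.7


@dataclass
class MotilitySummary:
    track_id: str
    v_inst: np.ndarray
    chi: Optional[float]
    t_c: Optional[float]
    d_n: Optional[float]


def downsample(traj: Trajectory, interval: float) -> Trajectory:
    """Keep the samples nearest to multiples of ``interval`` from the start.

    The first and last samples are always preserved.  ``interval`` must be
    at least the native sampling step.
    """
    t = traj.times
    if len(t) < 2:
        return traj
    native = float(np.min(np.diff(t)))
    if interval < native - 1e-9:
        raise InvalidIntervalError(
            f"interval {interval} shorter than native step {native}")
    targets = np.arange(t[0], t[-1] + 0.5 * interval, interval)
    nearest = [int(np.argmin(np.abs(t - tt))) for tt in targets]
    idx = np.unique(np.array(nearest + [0, len(t) - 1]))
    return Trajectory(track_id=traj.track_id, times=t[idx],
                      positions=traj.positions[idx], d_n=traj.d_n, t_c=traj.t_c)


def instantaneous_velocities(traj: Trajectory) -> np.ndarray:
    """Per consecutive pair, Euclidean displacement over time gap (um/s)."""
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 samples for velocities")
    d = np.diff(traj.positions, axis=0)
    dt = np.diff(traj.times)
    return np.hypot(d[:, 0], d[:, 1]) / dt


def directionality(traj: Trajectory) -> Optional[float]:
    """chi = net end-to-end displacement / summed path length, in [0, 1].

    Returns None (excluded from bins) when the path length is zero.
    """
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 samples for chi")
    d = np.diff(traj.positions, axis=0)
    L = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    if L == 0.0:
        return None
    net = float(np.hypot(*(traj.positions[-1] - traj.positions[0])))
    chi = net / L
    return min(chi, 1.0)


def msd(traj: Trajectory) -> MsdCurve:
    """Mean squared displacement with overlapping windows.

    The lag grid is integer multiples of the sampling interval up to 3/4 of
    the track duration (an empirical cutoff: longer lags have too few
    window pairs to average reliably).
    """
    n = len(traj)
    if n < 3:
        raise InsufficientDataError("need >= 3 samples for msd")
    dt_mean = traj.duration / (n - 1)
    k_max = max(1, int(math.floor(0.75 * (n - 1))))
    lags, vals, pairs = [], [], []
    p = traj.positions
    for k in range(1, k_max + 1):
        d = p[k:] - p[:-k]
        vals.append(float(np.mean(np.sum(d * d, axis=-1))))
        lags.append(k * dt_mean)
        pairs.append(n - k)
    return MsdCurve(lags=np.array(lags), msd=np.array(vals), n_pairs=np.array(pairs))


def ensemble_msd(trajs: Sequence[Trajectory]) -> MsdCurve:
    """Pair-weighted average of per-track msd curves on a common lag grid.

    Tracks are assumed to share a (roughly) common sampling interval; lags
    are pooled by index, each track contributing up to its own 3/4-duration
    cutoff.  The lag time of index k is the pair-weighted mean of the
    tracks' k-th lag times.
    """
    acc: dict[int, list[tuple[float, float, int]]] = {}
    for tr in trajs:
        if len(tr) < 3:
            continue
        c = msd(tr)
        for k, (lag, m, np_) in enumerate(zip(c.lags, c.msd, c.n_pairs), start=1):
            acc.setdefault(k, []).append((lag, m, int(np_)))
    if not acc:
        raise InsufficientDataError("no track long enough for msd")
    lags, vals, pairs = [], [], []
    for k in sorted(acc):
        rows = acc[k]
        w = np.array([r[2] for r in rows], dtype=float)
        lags.append(float(np.average([r[0] for r in rows], weights=w)))
        vals.append(float(np.average([r[1] for r in rows], weights=w)))
        pairs.append(int(w.sum()))
    return MsdCurve(lags=np.array(lags), msd=np.array(vals), n_pairs=np.array(pairs))


def fit_msd_drift(curve: MsdCurve) -> MsdDriftFit:
    """Bounded least squares of <r^2> = 4 D_eff lag + (v_eff lag)^2."""
    lags, y = curve.lags, curve.msd
    if len(lags) < 3:
        raise InsufficientDataError("need >= 3 lags")
    if np.allclose(y, 0.0):
        return MsdDriftFit(D_eff=0.0, v_eff=0.0, residual=0.0)

    def model(t, D, v):
        return 4.0 * D * t + (v * t) ** 2

    # initial guess from a linear fit in lag and lag^2
    A = np.column_stack([4.0 * lags, lags ** 2])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    p0 = [max(coef[0], 1e-12), math.sqrt(max(coef[1], 1e-18))]
    popt, _ = optimize.curve_fit(model, lags, y, p0=p0,
                                 bounds=([0.0, 0.0], [np.inf, np.inf]),
                                 method="trf", maxfev=20000)
    res = float(np.sqrt(np.mean((model(lags, *popt) - y) ** 2)))
    return MsdDriftFit(D_eff=float(popt[0]), v_eff=float(popt[1]), residual=res)


def fit_msd_anomalous(curve: MsdCurve, alpha_bounds=(0.0, 2.0)) -> MsdAnomalousFit:
    """Bounded least squares of <r^2> = 4 D' t^alpha with alpha in [0, 2]."""
    keep = curve.msd > 0
    lags, y = curve.lags[keep], curve.msd[keep]
    if len(lags) < 3:
        raise InsufficientDataError("need >= 3 positive msd points")
    # log-log regression seeds the nonlinear fit and is exact on power laws
    slope, intercept = np.polyfit(np.log(lags), np.log(y), 1)
    a0 = float(np.clip(slope, *alpha_bounds))
    D0 = max(math.exp(intercept) / 4.0, 1e-15)

    def model(t, D, a):
        return 4.0 * D * np.power(t, a)

    popt, _ = optimize.curve_fit(model, lags, y, p0=[D0, a0],
                                 bounds=([0.0, alpha_bounds[0]], [np.inf, alpha_bounds[1]]),
                                 method="trf", maxfev=20000)
    res = float(np.sqrt(np.mean((model(lags, *popt) - y) ** 2)))
    return MsdAnomalousFit(D_prime=float(popt[0]), alpha=float(popt[1]), residual=res)


def fit_distance_time(traj: Trajectory) -> DistanceTimeFit:
    """Fit distance-from-nucleation-site vs time to the saturating form.

    d(t) = d_max t^n / (T_half^n + t^n); n > 1 is read as pulling
    (sigmoid profile), n <= 1 as pushing (parabolic).  Fits with
    R^2 <= 0.7 are flagged unreliable.
    """
    if len(traj) < 4:
        raise InsufficientDataError("need >= 4 samples")
    t = traj.times - traj.times[0]
    d = np.hypot(*(traj.positions - traj.positions[0]).T)
    if np.allclose(d, 0.0):
        raise InsufficientDataError("degenerate all-zero distance series")

    def model(tt, dmax, thalf, n):
        tt = np.maximum(tt, 0.0)
        tn = np.power(tt, n)
        return dmax * tn / (np.power(thalf, n) + tn)

    dmax0 = max(float(d.max()), 1e-6)
    # T_half guess: first time distance exceeds half its maximum
    above = np.nonzero(d >= 0.5 * dmax0)[0]
    thalf0 = float(t[above[0]]) if len(above) and t[above[0]] > 0 else max(float(t[-1]) / 4, 1.0)
    best = None
    for n0 in (0.7, 1.5, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                model, t, d, p0=[dmax0, thalf0, n0],
                bounds=([1e-9, 1e-6, 0.05], [10 * dmax0 + 1, 100 * float(t[-1]) + 1, 12.0]),
                method="trf", maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((model(t, *popt) - d) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError("distance-time fit failed to converge")
    popt, sse = best
    sst = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    n = float(popt[2])
    return DistanceTimeFit(d_max=float(popt[0]), T_half=float(popt[1]), n=n,
                           R2=r2, mode="pulling" if n > 1 else "pushing",
                           reliable=r2 > 0.7)


def radial_profile(trajs: Iterable[Trajectory], r_cell: float,
                   bin_width: float = 5.0, measure: str = "chi") -> pd.DataFrame:
    """Binned mean +/- s.d. of chi (per track) or speed (per step) vs radius.

    chi is assigned to the radial bin of the track's first (nucleation)
    position; each instantaneous speed to the bin of the position at the
    start of its step.  Empty bins are absent from the output.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    edges = np.arange(0.0, r_cell + bin_width, bin_width)
    values: dict[int, list[float]] = {}
    for tr in trajs:
        if len(tr) < 2:
            continue
        if measure == "chi":
            chi = directionality(tr)
            if chi is None:
                continue
            r0 = float(np.hypot(*tr.positions[0]))
            b = min(int(r0 // bin_width), len(edges) - 2)
            values.setdefault(b, []).append(chi)
        elif measure == "v":
            v = instantaneous_velocities(tr)
            r = tr.radial_distances()[:-1]
            for b, val in zip(np.minimum((r // bin_width).astype(int), len(edges) - 2), v):
                values.setdefault(int(b), []).append(float(val))
        else:
            raise ValueError(f"unknown measure {measure!r}")
    rows = []
    for b in sorted(values):
        vals = np.array(values[b])
        rows.append({"r_lo": edges[b], "r_hi": edges[b + 1],
                     "r_mid": 0.5 * (edges[b] + edges[b + 1]),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "n": len(vals)})
    return pd.DataFrame(rows, columns=["r_lo", "r_hi", "r_mid", "mean", "sd", "n"])


def fit_lognormal_velocity(speeds) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit; returns linear-scale (mean, variance).

    Non-positive speeds are excluded.  The ML fit is done in log space
    (location pinned at zero) and transformed back: for log-mean m and
    log-sd s, mean = exp(m + s^2/2) and var = (exp(s^2) - 1) exp(2m + s^2).
    """
    v = np.asarray(speeds, dtype=float)
    v = v[v > 0]
    if len(v) < 10:
        raise InsufficientDataError("need >= 10 positive speeds")
    logs = np.log(v)
    m = float(np.mean(logs))
    s2 = float(np.var(logs))
    mean = math.exp(m + s2 / 2.0)
    var = (math.exp(s2) - 1.0) * math.exp(2.0 * m + s2)
    return mean, var


def radial_density(positions, r_cell: float, bin_width: float = 5.0) -> pd.DataFrame:
    """Counts per radial annulus divided by annulus area, unit total mass.

    The returned ``density`` integrates to 1 over the cell disk:
    sum(density_b * area_b) = 1.
    """
    positions = np.asarray(positions, dtype=float)
    r = np.hypot(positions[:, 0], positions[:, 1])
    edges = np.arange(0.0, r_cell + bin_width, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    total = counts.sum()
    dens = counts / (total * areas) if total > 0 else np.zeros_like(areas)
    return pd.DataFrame({"r_lo": edges[:-1], "r_hi": edges[1:],
                         "count": counts, "density": dens})


def summarize_track(traj: Trajectory) -> MotilitySummary:
    """Bundle the per-track motility measures used throughout the analysis."""
    return MotilitySummary(
        track_id=traj.track_id,
        v_inst=instantaneous_velocities(traj) if len(traj) >= 2 else np.array([]),
        chi=directionality(traj) if len(traj) >= 2 else None,
        t_c=traj.t_c,
        d_n=traj.d_n,
    )
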