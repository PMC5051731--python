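"""Synthetic pseudo-experimental MTOC datasets.

The experimental trajectories this pipeline was designed around (confocal
tracks of ~100 MTOCs in a 40 um mouse oocyte, frames every 3-4 minutes,
total observation under ~8000 s) are not publicly archived.  This module
generates datasets with the same statistical structure so every downstream
stage is testable: RWD trajectories under chosen drift fields, downsampled
to jittered frame intervals with isotropic Gaussian localization noise,
plus the binned chi(r) and capture-time reference structures the gradient
optimizer consumes, and the uniform-density MTOC position set emulating
the enucleated-oocyte control.

Defaults (30 tracks, 180-240 s jittered frames, 0.2 um localization noise)
are fixed emulation choices, recorded in the dataset metadata; the true
experimental track count and noise floor are unknown.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fields import DriftField
from .motility import radial_profile
from .optimize import Reference, capture_time_histogram
from .rwd import RwdParams, Trajectory, simulate_rwd

__all__ = ["SyntheticSpec", "OPTIMAL_ATTRACT", "OPTIMAL_REPEL",
           "generate_pseudo_experiment", "generate_enucleated_control"]

# Optimal drift fields from the rank-minimization fit: long-range
# attraction from the chromatin edge, short-range repulsion at the cortex.
OPTIMAL_ATTRACT = DriftField(r_half=10.0, s=1.0, origin="chromatin_edge")
OPTIMAL_REPEL = DriftField(r_half=0.0, s=2.0, origin="cell_boundary")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one pseudo-experimental dataset."""

    n_tracks: int = 30
    frame_interval: tuple[float, float] = (180.0, 240.0)  # jitter range, s
    duration: float = 8000.0          # s
    noise_sd: float = 0.2             # um localization noise
    generator: str = "rwd_optimal"    # or "rwd_custom", "uniform_static"
    attract: Optional[DriftField] = None   # for rwd_custom
    repel: Optional[DriftField] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval[0] < 60.0:
            raise ValueError("frame_interval must be >= 60 s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration > 8000.0 + 1e-9:
            raise ValueError("duration must be <= 8000 s")


def apply_observation_model(trajs, rng: np.random.Generator,
                            frame_interval: tuple[float, float],
                            noise_sd: float, r_cell: float = 40.0):
    """Degrade ideal tracks to the measurement process of the dataset:
    jittered frame sampling plus isotropic localization noise.

    Used both to build pseudo-experimental datasets and to push candidate
    simulations through the same observation model during optimization,
    so binned statistics are compared like with like.
    """
    lo, hi = frame_interval
    out = []
    for tr in trajs:
        sub = _resample_jittered(tr, rng, lo, hi)
        out.append(_add_noise(sub, rng, noise_sd, r_cell))
    return out


def _resample_jittered(traj: Trajectory, rng: np.random.Generator,
                       lo: float, hi: float) -> Trajectory:
    """Keep the recorded samples nearest to jittered frame times."""
    t = traj.times
    frame_times = [t[0]]
    while frame_times[-1] < t[-1]:
        frame_times.append(frame_times[-1] + rng.uniform(lo, hi))
    idx = np.unique([int(np.argmin(np.abs(t - ft))) for ft in frame_times] + [len(t) - 1])
    return Trajectory(track_id=traj.track_id, times=t[idx],
                      positions=traj.positions[idx], d_n=traj.d_n, t_c=traj.t_c)


def _add_noise(traj: Trajectory, rng: np.random.Generator, sd: float,
               r_cell: float) -> Trajectory:
    """Isotropic Gaussian localization noise, re-drawn to stay in the cell."""
    if sd == 0:
        return traj
    pos = traj.positions.copy()
    for i in range(len(pos)):
        for _ in range(100):
            cand = pos[i] + rng.normal(0.0, sd, size=2)
            if np.hypot(*cand) <= r_cell:
                pos[i] = cand
                break
    return Trajectory(track_id=traj.track_id, times=traj.times, positions=pos,
                      d_n=traj.d_n, t_c=traj.t_c)


def generate_pseudo_experiment(
        spec: SyntheticSpec,
        params: Optional[RwdParams] = None,
        chi_bin_width: float = 5.0,
        tc_bin_width: float = 600.0) -> tuple[list[Trajectory], Reference]:
    """Emulated experimental tracks plus optimizer reference structures.

    Runs the RWD model at fine time step with the chosen drift fields and
    the reference motility constants, downsamples each track to jittered
    frame intervals, adds localization noise, and bins chi(r) (mean, sd,
    count per radial bin) and capture-time frequencies (with binomial
    standard-error estimates) from the noisy tracks.
    """
    rng = np.random.default_rng(spec.seed)
    if params is None:
        params = RwdParams()
    params = dataclasses.replace(params, N_p=spec.n_tracks, T=spec.duration,
                                 seed=int(rng.integers(2 ** 31)))

    if spec.generator == "rwd_optimal":
        attract, repel = OPTIMAL_ATTRACT, OPTIMAL_REPEL
    elif spec.generator == "rwd_custom":
        attract, repel = spec.attract, spec.repel
    elif spec.generator == "uniform_static":
        attract = repel = None
        params = dataclasses.replace(params, D_eff=0.0, v_eff=0.0)
    else:
        raise ValueError(f"unknown generator {spec.generator!r}")

    fine = simulate_rwd(params, attract, repel, record_interval=10.0)
    tracks = apply_observation_model(fine, rng, spec.frame_interval,
                                     spec.noise_sd, params.r_cell)
    for i, tr in enumerate(tracks):
        tr.track_id = f"exp{i:04d}"

    prof = radial_profile(tracks, r_cell=params.r_cell, bin_width=chi_bin_width,
                          measure="chi")
    n_bins = int(math.ceil(params.r_cell / chi_bin_width))
    chi_edges = np.arange(0.0, (n_bins + 1) * chi_bin_width, chi_bin_width)
    chi_mean = np.full(n_bins, np.nan)
    chi_sd = np.full(n_bins, np.nan)
    chi_n = np.zeros(n_bins)
    for _, row in prof.iterrows():
        b = int(row.r_lo // chi_bin_width)
        chi_mean[b], chi_sd[b], chi_n[b] = row["mean"], row["sd"], row["n"]
    # bins wholly inside the chromatin disk are localization-noise
    # artifacts (an MTOC there is captured, not nucleated): drop them
    inside = chi_edges[1:] <= params.r_chr + 1e-9
    chi_mean[inside] = np.nan
    chi_sd[inside] = np.nan
    chi_n[inside] = 0
    # single-track bins carry no spread estimate; use the pooled sd
    pooled = np.nanmean(np.where(chi_n > 1, chi_sd, np.nan))
    chi_sd = np.where((chi_n > 0) & ((chi_n < 2) | (chi_sd == 0)),
                      pooled if np.isfinite(pooled) else 0.1, chi_sd)

    tc_edges = np.arange(0.0, spec.duration + tc_bin_width, tc_bin_width)
    tc_freq, tc_counts = capture_time_histogram(tracks, tc_edges)
    n = len(tracks)
    # binomial uncertainty with a half pseudocount, so bins with zero
    # observed captures carry a realistic (not vanishing) band
    f_tilde = (tc_counts + 0.5) / (n + 1.0)
    tc_sd = np.sqrt(f_tilde * (1.0 - f_tilde) / n)

    reference = Reference(chi_edges=chi_edges, chi_mean=chi_mean, chi_sd=chi_sd,
                          chi_n=chi_n, tc_edges=tc_edges, tc_freq=tc_freq,
                          tc_sd=tc_sd, tc_counts=tc_counts, n_tracks=n,
                          frame_interval=spec.frame_interval,
                          noise_sd=spec.noise_sd)
    return tracks, reference


def generate_enucleated_control(n_points: int, r_cell: float = 40.0,
                                seed: int = 0) -> np.ndarray:
    """Uniform-by-area MTOC positions over the cell disk.

    Emulates the enucleated-oocyte control, where MTOCs lose directional
    motility and distribute with uniform density; the expected mean radial
    distance is (2/3) r_cell.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    r = r_cell * np.sqrt(rng.uniform(size=n_points))
    ang = rng.uniform(0.0, 2.0 * math.pi, size=n_points)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])
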