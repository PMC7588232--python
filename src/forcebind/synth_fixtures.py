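"""Ground-truth-labeled synthetic inputs for both pipelines.

No raw movies or trap recordings accompany the assays this package
quantifies, so every stage is validated against synthetic data with known
ground truth:

* ``synth_movie`` renders dual-channel TIRF-like movies of filaments as
  Gaussian-profiled line segments.  Each filament carries a true ABP/actin
  ratio (the ABP-channel amplitude is ``true_ratio`` times the actin
  amplitude), a birth/death frame and a drift velocity; frames get a
  configurable background (constant, linear ramp, or smooth blobs),
  Poisson shot noise and Gaussian read noise.
* ``synth_tether`` emulates a constant-velocity pulling recording: a linear
  force ramp with instantaneous ruptures at each filament's breaking
  force, per-frame intensity ratios following a logistic (sigmoidal)
  force-binding response r(F) = r0 + dr / (1 + exp(-(F - F_th)/w)), and
  per-frame actin line scans.  The multi-filament tether configurations
  are reproduced: (1) several both-end-attached filaments of different
  lengths give multiple rupture peaks; (2) a dangling filament end gives
  an internal line-scan step; (3) parallel equal-length filaments give a
  single high-force rupture.

All generators are pure functions of (spec, seed).  The logistic response
is a generator assumption — the simplest monotone step with a width
parameter — not a mechanistic claim, and the dimensionless ``true_ratio``
deliberately abstracts over binding stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ChannelStack
from .trap_analysis import ForceTrace, FrameSeries

__all__ = [
    "SyntheticFilamentSpec",
    "SyntheticTetherSpec",
    "synth_movie",
    "synth_tether",
    "synth_force_response_points",
    "default_filament_specs",
]


@dataclass(frozen=True)
class SyntheticFilamentSpec:
    """One rendered filament: a blurred line segment with a fixed true ratio."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]  # (row, col) pairs
    width_sigma: float = 1.0  # px, Gaussian cross-section
    actin_amplitude: float = 300.0  # peak intensity above background
    true_ratio: float = 1.0  # ABP amplitude = true_ratio * actin amplitude
    birth_frame: int = 0
    death_frame: int = 10**9  # exclusive
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (d_row, d_col) px

    def __post_init__(self) -> None:
        if not self.birth_frame < self.death_frame:
            raise ValueError("birth_frame must precede death_frame")
        if not self.actin_amplitude > 0:
            raise ValueError("actin_amplitude must be > 0")
        if self.true_ratio < 0:
            raise ValueError("true_ratio must be >= 0")
        if not self.width_sigma > 0:
            raise ValueError("width_sigma must be > 0")


Configuration = Literal["single", 1, 2, 3]


@dataclass(frozen=True)
class SyntheticTetherSpec:
    """One synthetic pulling recording.

    ``configuration`` selects the tether geometry: ``"single"`` one
    filament; 1 several both-end-attached filaments of different lengths
    (sequential rupture peaks); 2 a dangling filament end (line-scan
    step); 3 parallel equal-length filaments (single high-force rupture).
    """

    configuration: Configuration = "single"
    breaking_forces: tuple[float, ...] = (6.0,)  # pN, one per rupture peak
    ramp_rate: float = 1.0  # pN/s
    r0: float = 0.2  # baseline ratio
    dr: float = 0.6  # response amplitude; 0 => flat (force-insensitive) control
    f_th: float = 1.0  # pN, response threshold
    # gradual transition: binding keeps rising visibly over the ramp, the
    # within-recording behavior the paired low/high-force windows probe
    width: float = 1.0  # pN, response width
    noise_sd: float = 0.05  # ratio noise per frame
    force_noise_sd: float = 0.05  # pN per 200 Hz sample
    line_scan_length: int = 60  # px
    dangling_fraction: float = 0.5  # config 2: fraction of scan with extra filament

    def __post_init__(self) -> None:
        if self.configuration in (1, 3) and len(self.breaking_forces) < 2 and self.configuration == 1:
            raise ValueError("configuration 1 needs >= 2 breaking forces")
        if self.configuration == "single" and len(self.breaking_forces) != 1:
            raise ValueError("single-filament tether has exactly one breaking force")
        if not self.ramp_rate > 0:
            raise ValueError("ramp_rate must be > 0")
        if not self.width > 0:
            raise ValueError("width must be > 0")


def _segment_distance(
    rows: np.ndarray, cols: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each pixel to the segment p0-p1."""
    d = p1 - p0
    length2 = float(d @ d)
    if length2 == 0:
        return np.hypot(rows - p0[0], cols - p0[1])
    t = ((rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]) / length2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rows - (p0[0] + t * d[0]), cols - (p0[1] + t * d[1]))


def _background(
    model: str, shape: tuple[int, int], level: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    if model == "constant":
        return np.full(shape, level)
    if model == "ramp":  # linear gradient across columns
        return level * (0.5 + np.tile(np.linspace(0, 1, w), (h, 1)))
    if model == "blobs":  # smooth large-scale structure
        from scipy.ndimage import gaussian_filter

        rough = rng.uniform(0, 2 * level, size=shape)
        return gaussian_filter(rough, sigma=min(h, w) / 6)
    raise ValueError(f"unknown background model {model!r}")


def synth_movie(
    specs: Sequence[SyntheticFilamentSpec],
    shape: tuple[int, int] = (128, 128),
    n_frames: int = 20,
    background_model: str = "constant",
    background_level: float = 100.0,
    read_noise_sd: float = 2.0,
    shot_noise: bool = True,
    frame_interval: float = 2.0,
    seed: int = 0,
) -> tuple[ChannelStack, ChannelStack, pd.DataFrame]:
    """Render a dual-channel synthetic movie and its ground-truth table.

    Returns (actin stack, ABP stack, truth table).  The truth table has one
    row per (filament, live frame) with the filament id, its true ratio and
    its centroid path.  Identical seeds give bit-identical output.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    actin = np.zeros((n_frames, h, w))
    abp = np.zeros((n_frames, h, w))
    truth_rows = []
    for fid, spec in enumerate(specs):
        p0 = np.asarray(spec.endpoints[0], dtype=float)
        p1 = np.asarray(spec.endpoints[1], dtype=float)
        drift = np.asarray(spec.drift_per_frame, dtype=float)
        for t in range(n_frames):
            if not (spec.birth_frame <= t < spec.death_frame):
                continue
            q0, q1 = p0 + t * drift, p1 + t * drift
            for q in (q0, q1):
                if not (0 <= q[0] < h and 0 <= q[1] < w):
                    raise ValueError(f"filament {fid} outside frame at frame {t}")
            dist = _segment_distance(rows, cols, q0, q1)
            profile = np.exp(-0.5 * (dist / spec.width_sigma) ** 2)
            actin[t] += spec.actin_amplitude * profile
            abp[t] += spec.true_ratio * spec.actin_amplitude * profile
            truth_rows.append(
                dict(
                    filament_id=fid,
                    frame=t,
                    true_ratio=spec.true_ratio,
                    centroid_row=float(0.5 * (q0[0] + q1[0])),
                    centroid_col=float(0.5 * (q0[1] + q1[1])),
                )
            )
    for t in range(n_frames):
        bg = _background(background_model, shape, background_level, rng)
        for stack in (actin, abp):
            signal = stack[t] + bg
            if shot_noise:
                signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
            if read_noise_sd > 0:
                signal = signal + rng.normal(0, read_noise_sd, size=shape)
            stack[t] = np.clip(signal, 0.0, None)
    truth = pd.DataFrame(
        truth_rows,
        columns=["filament_id", "frame", "true_ratio", "centroid_row", "centroid_col"],
    )
    return (
        ChannelStack(actin, frame_interval, channel_label="actin"),
        ChannelStack(abp, frame_interval, channel_label="abp"),
        truth,
    )


def default_filament_specs(
    true_ratios: Sequence[float] = (0.5, 1.5, 2.5),
    shape: tuple[int, int] = (192, 192),
    seed: int = 0,
) -> list[SyntheticFilamentSpec]:
    """Well-separated static filaments spanning the given true ratios."""
    h, w = shape
    rng = np.random.default_rng(seed)
    specs = []
    n = len(true_ratios)
    for i, ratio in enumerate(true_ratios):
        # place filaments on a coarse grid, away from edges
        row = 45 + (h - 90) * (i + 0.5) / n
        col0 = 45 + rng.uniform(0, 10)
        col1 = w - 45 - rng.uniform(0, 10)
        angle_jitter = rng.uniform(-6, 6)
        specs.append(
            SyntheticFilamentSpec(
                endpoints=((row + angle_jitter, col0), (row - angle_jitter, col1)),
                width_sigma=1.0,
                actin_amplitude=300.0,
                true_ratio=float(ratio),
                drift_per_frame=(rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)),
            )
        )
    return specs


@dataclass(frozen=True)
class TetherTruth:
    configuration: Configuration
    breaking_forces: tuple[float, ...]
    f_th: float
    final_breaking_force: float


def synth_tether(
    spec: SyntheticTetherSpec,
    frame_interval: float = 0.5,
    sample_rate: float = 200.0,
    seed: int = 0,
) -> tuple[ForceTrace, FrameSeries, np.ndarray, TetherTruth]:
    """Simulate one pulling recording.

    Force ramps linearly at ``ramp_rate``; at each breaking force the trace
    drops instantaneously to baseline and (configuration 1) resumes
    ramping until the next filament's breaking force.  Per-frame ratios
    follow the logistic binding response plus Gaussian noise.  Returns the
    force trace, the frame series (with frame-binned force), per-frame
    actin line scans and the truth record.
    """
    rng = np.random.default_rng(seed)
    bf = sorted(spec.breaking_forces)
    if spec.configuration in ("single", 2, 3):
        rupture_forces = [bf[-1]]  # one visible rupture peak
    else:  # configuration 1: sequential peaks
        rupture_forces = bf

    # build the combined-force trajectory as a sequence of ramps
    dt = 1.0 / sample_rate
    segments = []
    for peak in rupture_forces:
        n = max(int(round(peak / spec.ramp_rate / dt)), 2)
        segments.append(np.linspace(0.0, peak, n))
    # short post-rupture baseline tail
    tail = np.zeros(max(int(0.25 * sample_rate), 10))
    combined = np.concatenate(segments + [tail])
    combined = combined + rng.normal(0, spec.force_noise_sd, combined.size)
    times = np.arange(combined.size) * dt
    # both traps contribute equally (combined = mean of the two)
    trace = ForceTrace(times, combined.copy(), combined.copy())

    total_time = times[-1]
    n_frames = int(total_time // frame_interval)
    starts = np.arange(n_frames) * frame_interval
    frame_times = np.column_stack([starts, starts + frame_interval])
    # frame force from the noiseless trajectory for the response; binned
    # force for the series comes from the actual trace via the analysis path
    from .trap_analysis import bin_force

    force_per_frame = bin_force(trace, frame_times)
    response = spec.r0 + spec.dr / (1.0 + np.exp(-(force_per_frame - spec.f_th) / spec.width))
    ratios = response + rng.normal(0, spec.noise_sd, n_frames)
    frames = FrameSeries(frame_times, ratios, force_per_frame)

    # actin line scans: flat for single/1/3; internal step for config 2
    L = spec.line_scan_length
    base = 200.0
    profile = np.full(L, base)
    if spec.configuration == 2:
        cut = int(L * spec.dangling_fraction)
        profile[cut:] = base / 2  # non-bridging filament ends mid-tether
    elif spec.configuration in (1, 3):
        profile *= len(bf)  # brighter multi-filament tether, no internal step
    scans = np.tile(profile, (n_frames, 1)) + rng.normal(0, 2.0, (n_frames, L))

    truth = TetherTruth(spec.configuration, tuple(bf), spec.f_th, float(rupture_forces[-1]))
    return trace, frames, scans, truth


def synth_force_response_points(
    n_points: int = 200,
    f_max: float = 3.5,
    r0: float = 0.2,
    dr: float = 0.6,
    f_th: float = 1.0,
    width: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Pooled (force, normalized ratio) points with a logistic step response.

    Emulates the pooled single-filament scatter used for threshold
    detection: forces uniform on [0, f_max], ratios logistic in force plus
    noise, normalized by the maximum.  ``dr = 0`` gives the flat
    (force-insensitive) control.  Returns (points, true threshold).
    """
    rng = np.random.default_rng(seed)
    force = rng.uniform(0.0, f_max, n_points)
    ratio = r0 + dr / (1.0 + np.exp(-(force - f_th) / width))
    ratio = ratio + rng.normal(0, noise_sd, n_points)
    ratio = ratio / ratio.max()
    return np.column_stack([force, ratio]), f_th
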