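"""Correlative optical-trap force and confocal fluorescence analysis.

A tether (one or more actin filaments suspended between two trapped beads)
is pulled at constant velocity while 200 Hz force data from both traps and
two-channel confocal frames are recorded.  This module implements the
downstream quantification:

* binning the two-trap mean force to the confocal frame interval,
* rupture-event detection (a monotonic ramp followed by an instantaneous
  drop) and the final breaking force,
* multi-filament tether identification and exclusion: multiple rupture
  peaks (several both-end-attached filaments of different lengths),
  internal steps in the actin line scan (dangling filament ends), and
  breaking forces >= 16.5 pN (parallel filaments of equal length); only
  ``single_candidate`` tethers enter the per-filament analysis,
* paired low-/high-force averages: the mean intensity ratio of the five
  frames before final rupture versus the five frames immediately preceding
  that window,
* per-recording normalization by the maximum ratio, and
* K-means (k=2) detection of the force threshold separating
  force-uncorrelated from activated binding, with silhouette diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .stats_core import silhouette_scores

__all__ = [
    "ForceTrace",
    "FrameSeries",
    "RuptureEvent",
    "TetherRecording",
    "PairedAverages",
    "ThresholdResult",
    "bin_force",
    "detect_ruptures",
    "detect_line_scan_steps",
    "classify_tether",
    "paired_force_averages",
    "normalize_recording",
    "kmeans_force_threshold",
    "split_by_threshold",
]

Classification = Literal["single_candidate", "multi_peak", "dangling_filament", "high_force"]


@dataclass(frozen=True)
class ForceTrace:
    """Force time series from the two traps, uniformly sampled (default 200 Hz)."""

    times: np.ndarray  # s
    force_trap1: np.ndarray  # pN
    force_trap2: np.ndarray  # pN

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f1 = np.asarray(self.force_trap1, dtype=float)
        f2 = np.asarray(self.force_trap2, dtype=float)
        if not (t.shape == f1.shape == f2.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("times and forces must be equal-length 1-D arrays (n >= 2)")
        dt = np.diff(t)
        if not (dt > 0).all():
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly sampled")
        if not (np.isfinite(f1).all() and np.isfinite(f2).all()):
            raise ValueError("forces must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "force_trap1", f1)
        object.__setattr__(self, "force_trap2", f2)

    @property
    def combined(self) -> np.ndarray:
        """Two-trap average force, the quantity binned to frames."""
        return 0.5 * (self.force_trap1 + self.force_trap2)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class FrameSeries:
    """Per-confocal-frame ratios with frame-binned force."""

    frame_times: np.ndarray  # (n, 2) start/end seconds
    ratio: np.ndarray  # background-subtracted I_ABD/I_actin per frame
    force: np.ndarray  # mean combined force per frame, pN

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        if ft.ndim != 2 or ft.shape[1] != 2:
            raise ValueError("frame_times must be (n, 2) start/end pairs")
        if not (ft[:, 1] > ft[:, 0]).all():
            raise ValueError("frame end must follow start")
        if (ft[1:, 0] < ft[:-1, 1] - 1e-12).any():
            raise ValueError("frames must be non-overlapping and time-ordered")
        self.frame_times = ft
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.force = np.asarray(self.force, dtype=float)

    def __len__(self) -> int:
        return self.frame_times.shape[0]


@dataclass(frozen=True)
class RuptureEvent:
    time: float  # s, at the last pre-drop sample
    force_drop: float  # pN
    index: int  # sample index of the last pre-drop sample


@dataclass
class TetherRecording:
    """One trapped-filament pulling experiment with its classification."""

    frame_series: FrameSeries
    rupture_events: list[RuptureEvent] = field(default_factory=list)
    final_breaking_force: Optional[float] = None  # pN
    actin_line_scans: Optional[np.ndarray] = None  # (n_frames, L) profiles
    classification: Optional[Classification] = None
    included: bool = False


@dataclass(frozen=True)
class PairedAverages:
    """Adjacent disjoint five-frame ratio averages before final rupture."""

    low_force_avg: float
    high_force_avg: float


@dataclass
class ThresholdResult:
    """Two-cluster partition of (force, normalized ratio) points."""

    labels: np.ndarray  # 0 = low-force cluster, 1 = high-force cluster
    threshold_force: float  # pN, midpoint between the clusters' force extremes
    silhouette_by_k: dict[int, Optional[float]]
    separating: bool  # True iff the clusters' force ranges do not overlap


def bin_force(trace: ForceTrace, frame_times: np.ndarray) -> np.ndarray:
    """Average the two-trap mean force over each confocal frame interval.

    A sample at time t belongs to frame [start, end) (the final frame is
    closed).  An interval containing no sample is an error naming the frame.
    """
    ft = np.asarray(frame_times, dtype=float)
    combined = trace.combined
    out = np.empty(ft.shape[0])
    for i, (start, end) in enumerate(ft):
        if i == ft.shape[0] - 1:
            sel = (trace.times >= start) & (trace.times <= end)
        else:
            sel = (trace.times >= start) & (trace.times < end)
        if not sel.any():
            raise ValueError(f"frame {i} [{start}, {end}] contains no force samples")
        out[i] = combined[sel].mean()
    return out


def detect_ruptures(
    trace: ForceTrace, drop_threshold: float = 1.0, window: int = 5
) -> tuple[list[RuptureEvent], Optional[float]]:
    """Detect rupture events in the combined force trace.

    An event is a drop of at least ``drop_threshold`` pN within at most
    ``window`` samples (25 ms at 200 Hz with defaults — effectively
    instantaneous).  Detected events are separated by at least ``window``
    samples.  Returns the events and the final breaking force: the force at
    the last sample before the final drop.
    """
    f = trace.combined
    n = f.size
    events: list[RuptureEvent] = []
    i = 0
    while i < n - 1:
        j_end = min(i + window, n - 1)
        seg_min = f[i + 1 : j_end + 1].min()
        if f[i] - seg_min >= drop_threshold:
            events.append(RuptureEvent(float(trace.times[i]), float(f[i] - seg_min), i))
            i += window  # enforce event separation
        else:
            i += 1
    final = float(f[events[-1].index]) if events else None
    return events, final


def detect_line_scan_steps(
    profile: np.ndarray, step_fraction: float = 0.3, min_plateau: int = 5
) -> int:
    """Count internal step-like intensity reductions along an actin line scan.

    At each internal position the means of the adjacent ``min_plateau``-px
    plateaus are compared; a step is a position where the following plateau
    drops to at most ``(1 - step_fraction)`` of the preceding one.  Runs of
    adjacent flagged positions are counted once.  Any internal step marks a
    dangling (non-bridging) filament end, implying a multi-filament tether.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 2 * min_plateau:
        raise ValueError("profile shorter than two plateaus")
    flags = np.zeros(p.size, dtype=bool)
    for i in range(min_plateau, p.size - min_plateau + 1):
        pre = p[i - min_plateau : i].mean()
        post = p[i : i + min_plateau].mean()
        if pre > 0 and post <= (1.0 - step_fraction) * pre:
            flags[i] = True
    # count runs of consecutive flagged positions as single steps
    return int(np.count_nonzero(flags[1:] & ~flags[:-1]) + (1 if flags[0] else 0))


def classify_tether(
    rec: TetherRecording,
    breaking_force_cutoff: float = 16.5,
    step_fraction: float = 0.3,
    min_plateau: int = 5,
) -> TetherRecording:
    """Assign the multi-filament exclusion classification to a recording.

    Priority: more than one rupture peak => ``multi_peak``; any internal
    line-scan step => ``dangling_filament``; final breaking force at or
    above the cutoff => ``high_force``; otherwise ``single_candidate``
    (the only class included in downstream per-filament analysis).
    """
    if not rec.rupture_events or rec.final_breaking_force is None:
        raise ValueError("no rupture: recording cannot be classified")
    if len(rec.rupture_events) > 1:
        rec.classification = "multi_peak"
    else:
        has_step = False
        if rec.actin_line_scans is not None:
            for profile in np.atleast_2d(rec.actin_line_scans):
                if detect_line_scan_steps(profile, step_fraction, min_plateau) > 0:
                    has_step = True
                    break
        if has_step:
            rec.classification = "dangling_filament"
        elif rec.final_breaking_force >= breaking_force_cutoff:
            rec.classification = "high_force"
        else:
            rec.classification = "single_candidate"
    rec.included = rec.classification == "single_candidate"
    return rec


def paired_force_averages(
    frames: FrameSeries,
    n_frames_before_rupture: Optional[int] = None,
    window: int = 5,
    min_frames: int = 10,
) -> PairedAverages:
    """Low- and high-force five-frame ratio averages before final rupture.

    ``n_frames_before_rupture`` limits the series to the frames acquired
    before the final tether ruptured (defaults to the whole series).  The
    high-force average is the mean ratio of the last ``window`` pre-rupture
    frames; the low-force average covers the ``window`` frames immediately
    preceding those.  Recordings with fewer than ``min_frames`` quantifiable
    frames are excluded.
    """
    ratios = frames.ratio
    if n_frames_before_rupture is not None:
        ratios = ratios[:n_frames_before_rupture]
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < min_frames:
        raise ValueError(
            f"only {ratios.size} quantifiable frames (< {min_frames}): excluded from paired analysis"
        )
    high = float(ratios[-window:].mean())
    low = float(ratios[-2 * window : -window].mean())
    return PairedAverages(low_force_avg=low, high_force_avg=high)


def normalize_recording(ratios: Sequence[float]) -> np.ndarray:
    """Divide a recording's ratios by its maximum (output max is exactly 1)."""
    r = np.asarray(ratios, dtype=float)
    finite = r[np.isfinite(r)]
    if finite.size == 0:
        raise ValueError("no defined ratios")
    m = finite.max()
    if m <= 0:
        raise ValueError("nonpositive maximum: cannot normalize")
    return r / m


def kmeans_force_threshold(
    points: np.ndarray,
    n_init: int = 50,
    seed: Optional[int] = 0,
    features: Literal["both", "force"] = "both",
) -> ThresholdResult:
    """K-means (k=2) force threshold on (force, normalized ratio) points.

    Coordinates are standardized to unit variance per axis before
    clustering (or the force axis alone with ``features='force'``).  The
    threshold force is the midpoint between the maximum force of the
    low-force cluster and the minimum force of the high-force cluster.
    When those force ranges overlap — a few transition-zone points landing
    on the "wrong" side — the result is flagged non-separating; the
    midpoint is still reported and remains a sensible boundary estimate
    for slight overlaps.  Silhouette scores for k in {2, 3, 4} are
    attached as the cluster-count diagnostic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): force, normalized ratio")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    scale = pts.std(axis=0, ddof=0)
    if (scale == 0).all():
        raise ValueError("degenerate input: all points identical")
    scale = np.where(scale == 0, 1.0, scale)
    z = (pts - pts.mean(axis=0)) / scale
    feats = z if features == "both" else z[:, :1]

    labels_by_k: dict[int, np.ndarray] = {}
    for k in (2, 3, 4):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels_by_k[k] = km.fit_predict(feats)
    sil = silhouette_scores(feats, labels_by_k)

    labels2 = labels_by_k[2]
    force = pts[:, 0]
    # orient labels so cluster 1 is the higher-force cluster
    if force[labels2 == 0].mean() > force[labels2 == 1].mean():
        labels2 = 1 - labels2
    lo_max = force[labels2 == 0].max()
    hi_min = force[labels2 == 1].min()
    separating = bool(lo_max < hi_min)
    threshold = float(0.5 * (lo_max + hi_min))
    return ThresholdResult(labels2, threshold, sil, separating)


def split_by_threshold(
    points: np.ndarray, threshold_force: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split ratios into below/at-or-above threshold force groups.

    Raises when either group is empty (the downstream KS comparison is
    undefined then).
    """
    pts = np.asarray(points, dtype=float)
    force, ratio = pts[:, 0], pts[:, 1]
    below = ratio[force < threshold_force]
    above = ratio[force >= threshold_force]
    if below.size == 0 or above.size == 0:
        raise ValueError("threshold outside the observed force range: empty group")
    return below, above
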