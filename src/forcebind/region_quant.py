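"""Filament-region detection, tracking and intensity-ratio quantification.

The TIRF force-reconstitution assay records dual-color movies of actin
filaments agitated by surface-anchored myosin motors, with a fluorescent
actin-binding-protein (ABP) construct in solution.  The readout per
filament region is the background-subtracted intensity ratio
I_ABP / I_actin, averaged over the frames in which the region is tracked.

Pipeline, applied to the actin channel to find regions:

1. preprocess each frame (unsharp mask, median filter, rolling-ball
   background subtraction),
2. binarize (Otsu by default) and label 8-connected components, discarding
   small components and components whose centroid is fewer than 30 px from
   a field-of-view edge (so the 60x60 background window always fits),
3. link regions across consecutive frames by nearest centroid under a
   24 px gate; a missed frame terminates a track,
4. keep tracks at least 10 consecutive frames long,
5. per frame and channel, subtract a local background (mean of the 60x60
   window pixels not covered by any detected region) from the region's
   mean intensity, form the per-frame ratio and its track average.

Intensities are always quantified on the *raw* frames; preprocessing only
drives segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, restoration

from .io_formats import ChannelStack, RunConfig

__all__ = [
    "RegionObservation",
    "RegionTrack",
    "BackgroundEstimate",
    "preprocess_frame",
    "segment_frame",
    "track_regions",
    "filter_tracks",
    "estimate_background",
    "compute_track_ratio",
    "summarize_chamber",
    "quantify_movie",
]


@dataclass(frozen=True)
class RegionObservation:
    """One segmented filament region in one frame."""

    frame: int
    pixels: np.ndarray  # (N, 2) int array of (row, col)
    centroid: tuple[float, float]
    area: int

    @classmethod
    def from_pixels(cls, frame: int, pixels: np.ndarray) -> "RegionObservation":
        pixels = np.asarray(pixels, dtype=int)
        if pixels.size == 0:
            raise ValueError("region has no pixels")
        centroid = (float(pixels[:, 0].mean()), float(pixels[:, 1].mean()))
        return cls(frame, pixels, centroid, int(pixels.shape[0]))


@dataclass
class RegionTrack:
    """A maximal run of region observations on strictly consecutive frames."""

    track_id: int
    observations: list[RegionObservation] = field(default_factory=list)
    per_frame_ratio: list[Optional[float]] = field(default_factory=list)
    bgsub_means: list[tuple[Optional[float], Optional[float]]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [o.frame for o in self.observations]

    @property
    def average_ratio(self) -> Optional[float]:
        """Mean of the defined per-frame ratios: the overall I_ABP/I_actin."""
        vals = [r for r in self.per_frame_ratio if r is not None]
        return float(np.mean(vals)) if vals else None

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Local background for one track observation in one frame."""

    frame: int
    track_id: int
    bg_actin: float
    bg_abp: float
    n_pixels_used: int

    @property
    def valid(self) -> bool:
        return self.n_pixels_used > 0


def preprocess_frame(frame: np.ndarray, params: RunConfig) -> np.ndarray:
    """Unsharp mask, median filter, then rolling-ball background subtraction.

    The output is clipped at zero: the rolling ball removes any smooth
    background (a flat frame maps to all zeros) while the sharpening and
    median steps respectively boost thin filaments and reject single-pixel
    shot noise.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite values")
    out = frame
    if params.unsharp_weight > 0 and params.unsharp_radius > 0:
        blurred = ndimage.gaussian_filter(out, sigma=params.unsharp_radius)
        out = out + params.unsharp_weight * (out - blurred)
    if params.median_radius > 0:
        size = 2 * params.median_radius + 1
        out = ndimage.median_filter(out, size=size)
    if params.rolling_ball_radius > 0:
        background = restoration.rolling_ball(out, radius=params.rolling_ball_radius)
        out = out - background
    return np.clip(out, 0.0, None)


def segment_frame(frame: np.ndarray, params: RunConfig) -> list[RegionObservation]:
    """Binarize a preprocessed frame and extract filament-region candidates.

    Components smaller than ``min_area`` px, and components whose centroid
    is fewer than ``edge_margin`` px from any image edge, are discarded.
    The edge rule guarantees the background window fits inside the image.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if params.threshold_method == "absolute":
        thresh = params.absolute_threshold
    else:
        if np.ptp(frame) == 0:  # Otsu undefined on a constant frame
            return []
        thresh = filters.threshold_otsu(frame)
    mask = frame > thresh
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=params.connectivity)
    regions: list[RegionObservation] = []
    m = params.edge_margin
    for prop in measure.regionprops(labels):
        if prop.area < params.min_area:
            continue
        cr, cc = prop.centroid
        if min(cr, cc, h - 1 - cr, w - 1 - cc) < m:
            continue  # too close to the field-of-view edge
        regions.append(
            RegionObservation(0, np.asarray(prop.coords, dtype=int), (float(cr), float(cc)), int(prop.area))
        )
    return regions


def _at_frame(obs: RegionObservation, frame: int) -> RegionObservation:
    return RegionObservation(frame, obs.pixels, obs.centroid, obs.area)


def track_regions(
    per_frame: Sequence[Sequence[RegionObservation]],
    gate_distance: float = 24.0,
) -> list[RegionTrack]:
    """Link per-frame regions into tracks by gated nearest-centroid matching.

    Matches within one frame transition are resolved greedily in ascending
    centroid-distance order (exact ties broken by lower track id), one
    observation per open track.  Unmatched observations open new tracks;
    an open track that receives no match is closed and never reopened, so
    track frames are strictly consecutive.
    """
    tracks: list[RegionTrack] = []
    open_tracks: list[RegionTrack] = []
    next_id = 0
    for f, observations in enumerate(per_frame):
        observations = [_at_frame(o, f) for o in observations]
        candidates = []
        for ti, tr in enumerate(open_tracks):
            pr, pc = tr.observations[-1].centroid
            for oi, obs in enumerate(observations):
                d = math.hypot(obs.centroid[0] - pr, obs.centroid[1] - pc)
                if d <= gate_distance:
                    candidates.append((d, tr.track_id, ti, oi))
        candidates.sort()  # ascending distance, then lower track_id
        used_tracks: set[int] = set()
        used_obs: set[int] = set()
        for d, _tid, ti, oi in candidates:
            if ti in used_tracks or oi in used_obs:
                continue
            open_tracks[ti].observations.append(observations[oi])
            used_tracks.add(ti)
            used_obs.add(oi)
        still_open = [tr for ti, tr in enumerate(open_tracks) if ti in used_tracks]
        for oi, obs in enumerate(observations):
            if oi not in used_obs:
                tr = RegionTrack(next_id, [obs])
                next_id += 1
                tracks.append(tr)
                still_open.append(tr)
        open_tracks = still_open
    return tracks


def filter_tracks(tracks: Sequence[RegionTrack], min_track_len: int = 10) -> list[RegionTrack]:
    """Keep only tracks detected in at least ``min_track_len`` consecutive frames."""
    return [t for t in tracks if len(t) >= min_track_len]


def estimate_background(
    frame_regions: Sequence[RegionObservation],
    target: RegionObservation,
    actin_frame: np.ndarray,
    abp_frame: np.ndarray,
    box: int = 60,
    track_id: int = -1,
) -> BackgroundEstimate:
    """Local background around one region, per channel.

    Mean intensity over the ``box`` x ``box`` window centered on the target
    centroid, excluding pixels of the target itself and of every other
    region detected in the frame.  If no pixels remain the estimate is
    flagged invalid (``n_pixels_used == 0``) and the caller marks the
    frame's ratio missing.
    """
    h, w = actin_frame.shape
    half = box // 2
    r0 = int(round(target.centroid[0])) - half
    c0 = int(round(target.centroid[1])) - half
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r0 + box, h), min(c0 + box, w)
    occupied = np.zeros((h, w), dtype=bool)
    for reg in frame_regions:
        occupied[reg.pixels[:, 0], reg.pixels[:, 1]] = True
    window = ~occupied[r0:r1, c0:c1]
    n = int(window.sum())
    if n == 0:
        return BackgroundEstimate(target.frame, track_id, float("nan"), float("nan"), 0)
    bg_a = float(actin_frame[r0:r1, c0:c1][window].mean())
    bg_b = float(abp_frame[r0:r1, c0:c1][window].mean())
    return BackgroundEstimate(target.frame, track_id, bg_a, bg_b, n)


def compute_track_ratio(
    track: RegionTrack,
    actin: ChannelStack,
    abp: ChannelStack,
    backgrounds: Sequence[BackgroundEstimate],
    epsilon_denominator: float = 0.0,
) -> RegionTrack:
    """Fill per-frame and average I_ABP/I_actin ratios for one track.

    Per frame: ratio = (mean ABP over region - bg_abp) / (mean actin over
    region - bg_actin).  Frames with an invalid background or a denominator
    of magnitude <= ``epsilon_denominator`` are marked missing and excluded
    from the average.
    """
    track.per_frame_ratio = []
    track.bgsub_means = []
    for obs, bg in zip(track.observations, backgrounds):
        if not bg.valid:
            track.per_frame_ratio.append(None)
            track.bgsub_means.append((None, None))
            continue
        rows, cols = obs.pixels[:, 0], obs.pixels[:, 1]
        mean_a = float(actin.frames[obs.frame][rows, cols].mean()) - bg.bg_actin
        mean_b = float(abp.frames[obs.frame][rows, cols].mean()) - bg.bg_abp
        track.bgsub_means.append((mean_a, mean_b))
        if abs(mean_a) <= epsilon_denominator:
            track.per_frame_ratio.append(None)
        else:
            track.per_frame_ratio.append(mean_b / mean_a)
    return track


def summarize_chamber(tracks: Sequence[RegionTrack]) -> float:
    """Per-movie summary: mean over tracks of the track-average ratio.

    This is the per-chamber value that enters the paired -ATP/+ATP test.
    """
    averages = [t.average_ratio for t in tracks if t.average_ratio is not None]
    if not averages:
        raise ValueError("no filament regions")
    return float(np.mean(averages))


def quantify_movie(
    actin: ChannelStack,
    abp: ChannelStack,
    params: Optional[RunConfig] = None,
) -> list[RegionTrack]:
    """Run the full pipeline on a dual-channel movie; returns filtered tracks
    with ratios filled.

    Channels must be aligned frame-for-frame and pixel-for-pixel; the actin
    channel drives segmentation and tracking.
    """
    params = params or RunConfig()
    if actin.frames.shape != abp.frames.shape:
        raise ValueError("channel stacks must share shape")
    per_frame: list[list[RegionObservation]] = []
    for t in range(actin.n_frames):
        pre = preprocess_frame(actin.frames[t], params)
        per_frame.append(segment_frame(pre, params))
    tracks = filter_tracks(
        track_regions(per_frame, params.gate_distance), params.min_track_len
    )
    for track in tracks:
        bgs = []
        for obs in track.observations:
            bgs.append(
                estimate_background(
                    per_frame[obs.frame],
                    obs,
                    actin.frames[obs.frame],
                    abp.frames[obs.frame],
                    box=params.background_box,
                    track_id=track.track_id,
                )
            )
        eps = params.epsilon_denominator_scale * float(np.ptp(actin.frames))
        compute_track_ratio(track, actin, abp, bgs, epsilon_denominator=eps)
    return tracks
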