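"""File formats and run configuration.

Movies are plain multi-page TIFF stacks, one per fluorescence channel
(actin and ABP), read without any intensity rescaling.  Quantification
results are written as two CSV tables: a *detail* table with one row per
(track, frame) and a *summary* table with one row per track.  All pixel
coordinates are 0-based ``(row, col)`` and frame indices are 0-based.

Run parameters live in a flat-per-module YAML file; loading a config echoes
the fully resolved parameter set to the log so every run is reproducible
from its sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("forcebind")

__all__ = [
    "ChannelStack",
    "RunConfig",
    "read_movie",
    "read_movie_pair",
    "write_region_table",
    "read_region_table",
]

# CSV floats use Python's shortest round-trip repr (up to 17 significant
# digits), so re-reading reproduces every float64 bit-for-bit.


@dataclass(frozen=True)
class ChannelStack:
    """A single-channel fluorescence movie: T frames of H x W intensities."""

    frames: np.ndarray  # (T, H, W) float64, finite, >= 0
    frame_interval: float  # seconds per frame
    pixel_size: Optional[float] = None  # length units per pixel
    channel_label: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if frames.shape[0] < 1:
            raise ValueError("stack has zero frames")
        if not np.isfinite(frames).all():
            raise ValueError("intensities must be finite")
        if (frames < 0).any():
            raise ValueError("intensities must be >= 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RunConfig:
    """All tunable parameters of the region and trap pipelines.

    Defaults equal the published protocol values where one is printed
    (tracking gate, minimum track length, edge margin, background box,
    sample rate, breaking-force cutoff); the remaining knobs default to
    standard values for ~1-px-wide fluorescent filaments.
    """

    # --- region_quant: preprocessing ---
    unsharp_radius: float = 2.0  # px
    unsharp_weight: float = 0.6
    median_radius: int = 1  # px
    rolling_ball_radius: float = 25.0  # px
    # --- region_quant: segmentation ---
    threshold_method: str = "otsu"  # "otsu" | "absolute"
    absolute_threshold: float = 0.0  # used when threshold_method == "absolute"
    connectivity: int = 2  # skimage connectivity: 2 => 8-connected
    min_area: int = 10  # px
    edge_margin: int = 30  # px; centroids closer to an edge are excluded
    # --- region_quant: tracking / quantification ---
    gate_distance: float = 24.0  # px
    min_track_len: int = 10  # frames
    background_box: int = 60  # px, square window side
    epsilon_denominator_scale: float = 1e-6  # x frame intensity range
    # --- trap_analysis ---
    sample_rate: float = 200.0  # Hz
    drop_threshold: float = 1.0  # pN
    drop_window: int = 5  # samples
    step_fraction: float = 0.3
    min_plateau: int = 5  # px
    breaking_force_cutoff: float = 16.5  # pN
    n_quantifiable_frames: int = 10
    window_frames: int = 5  # frames per low/high-force average
    kmeans_n_init: int = 50
    kmeans_features: str = "both"  # "both" (standardized) | "force"

    _RANGES = {
        "unsharp_radius": (0.0, 100.0),
        "unsharp_weight": (0.0, 10.0),
        "median_radius": (0, 50),
        "rolling_ball_radius": (0.0, 1000.0),
        "min_area": (1, 10**6),
        "edge_margin": (0, 10**4),
        "gate_distance": (0.0, 10**4),
        "min_track_len": (1, 10**6),
        "background_box": (2, 10**4),
        "sample_rate": (1e-9, 10**9),
        "drop_threshold": (0.0, 10**6),
        "drop_window": (1, 10**6),
        "step_fraction": (0.0, 1.0),
        "min_plateau": (1, 10**6),
        "breaking_force_cutoff": (0.0, 10**6),
        "n_quantifiable_frames": (2, 10**6),
        "window_frames": (1, 10**6),
        "kmeans_n_init": (1, 10**6),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v!r} outside legal range [{lo}, {hi}]")
        if self.threshold_method not in ("otsu", "absolute"):
            raise ValueError("threshold_method must be 'otsu' or 'absolute'")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if self.kmeans_features not in ("both", "force"):
            raise ValueError("kmeans_features must be 'both' or 'force'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config; unknown keys are an error, missing keys default."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # flat namespace per module
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**flat)
        logger.info("resolved run configuration: %s", json.dumps(cfg.to_dict()))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def read_movie(
    path: str | Path,
    channel_label: str = "",
    *,
    frame_interval: float = 2.0,
    pixel_size: Optional[float] = None,
) -> ChannelStack:
    """Read a multi-page TIFF as one channel, without rescaling intensities.

    Integer pixel types are widened to float64; values are preserved exactly.
    The default frame interval matches a 2 s acquisition cadence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path}: zero pages")
        shapes = {tuple(p.shape) for p in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"{path}: inconsistent page dimensions {sorted(shapes)}")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a (T, H, W) stack, got shape {arr.shape}")
    frames = arr.astype(np.float64)
    return ChannelStack(frames, frame_interval, pixel_size, channel_label)


def read_movie_pair(
    actin_path: str | Path,
    abp_path: Optional[str | Path] = None,
    *,
    interleaved: bool = False,
    frame_interval: float = 2.0,
    pixel_size: Optional[float] = None,
) -> tuple[ChannelStack, ChannelStack]:
    """Read the two channels of a dual-color movie.

    Either two single-channel files, or (``interleaved=True``) one file with
    an even page count read as alternating actin/ABP pages.
    """
    if interleaved:
        if abp_path is not None:
            raise ValueError("interleaved mode takes a single file")
        both = read_movie(actin_path, "interleaved", frame_interval=frame_interval)
        if both.n_frames % 2:
            raise ValueError("interleaved stack must have an even page count")
        actin = ChannelStack(both.frames[0::2], frame_interval, pixel_size, "actin")
        abp = ChannelStack(both.frames[1::2], frame_interval, pixel_size, "abp")
        return actin, abp
    if abp_path is None:
        raise ValueError("two files required unless interleaved=True")
    actin = read_movie(actin_path, "actin", frame_interval=frame_interval, pixel_size=pixel_size)
    abp = read_movie(abp_path, "abp", frame_interval=frame_interval, pixel_size=pixel_size)
    if actin.frames.shape != abp.frames.shape:
        raise ValueError("actin and ABP stacks differ in shape")
    return actin, abp


_DETAIL_COLUMNS = [
    "track_id",
    "frame",  # 0-based frame index
    "centroid_row",  # 0-based pixel coordinates
    "centroid_col",
    "area_px",
    "mean_actin_bgsub",
    "mean_abp_bgsub",
    "ratio",  # per-frame I_ABP / I_actin; empty when missing
]
_SUMMARY_COLUMNS = ["track_id", "n_frames", "average_ratio"]


def write_region_table(tracks: Iterable, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write detail and summary CSVs for a set of region tracks.

    ``<prefix>_detail.csv`` has one row per (track, frame) and
    ``<prefix>_summary.csv`` one row per track with its average ratio.
    Floats are written in shortest round-trip decimal form so a re-read
    reproduces every value bit-for-bit.
    """
    prefix = Path(path_prefix)
    detail_rows, summary_rows = [], []
    for track in tracks:
        for obs, ratio, (ma, mb) in zip(
            track.observations, track.per_frame_ratio, track.bgsub_means
        ):
            detail_rows.append(
                dict(
                    track_id=track.track_id,
                    frame=obs.frame,
                    centroid_row=obs.centroid[0],
                    centroid_col=obs.centroid[1],
                    area_px=obs.area,
                    mean_actin_bgsub=ma,
                    mean_abp_bgsub=mb,
                    ratio=ratio,
                )
            )
        summary_rows.append(
            dict(
                track_id=track.track_id,
                n_frames=len(track.observations),
                average_ratio=track.average_ratio,
            )
        )
    detail = pd.DataFrame(detail_rows, columns=_DETAIL_COLUMNS)
    summary = pd.DataFrame(summary_rows, columns=_SUMMARY_COLUMNS)
    detail_path = prefix.with_name(prefix.name + "_detail.csv")
    summary_path = prefix.with_name(prefix.name + "_summary.csv")
    detail.to_csv(detail_path, index=False)
    summary.to_csv(summary_path, index=False)
    return detail_path, summary_path


def read_region_table(path_prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-read the detail and summary CSVs written by :func:`write_region_table`."""
    prefix = Path(path_prefix)
    detail = pd.read_csv(prefix.with_name(prefix.name + "_detail.csv"))
    summary = pd.read_csv(prefix.with_name(prefix.name + "_summary.csv"))
    return detail, summary


def write_run_sidecar(path: str | Path, config: RunConfig, **metadata) -> None:
    """Write the JSON run-metadata sidecar (config echo, version, seeds)."""
    from . import __version__

    payload = {"software_version": __version__, "config": config.to_dict(), **metadata}
    Path(path).write_text(json.dumps(payload, indent=2))
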