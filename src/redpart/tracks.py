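"""Ingestion of tracked-trajectory tables and velocity estimation.

Empirical input is a delimited table of (frame, id, x, y) produced by
upstream tracking software, recorded at a known frame rate.  Velocities
are estimated with a Savitzky–Golay smoothing derivative (3rd order,
7-frame window at 30 fps by default), and dependence is analysed over a
fixed time window (±15 s by default) centered on a time of interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .observations import ObservationMatrix

__all__ = [
    "TrackTable",
    "AnalysisConfig",
    "read_tracks",
    "savgol_velocities",
    "window_observations",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("frame", "id", "x", "y")


@dataclass
class TrackTable:
    """Validated track table with ids normalized to 0..n-1."""

    data: pd.DataFrame = field(repr=False)
    fps: float
    id_mapping: dict = field(default_factory=dict)  # original -> normalized

    @property
    def n_individuals(self) -> int:
        return int(self.data["id"].nunique())

    @property
    def frame_range(self) -> tuple[int, int]:
        return int(self.data["frame"].min()), int(self.data["frame"].max())


@dataclass
class AnalysisConfig:
    """Windowed-analysis parameters, serialized alongside every result."""

    half_width_seconds: float = 15.0
    savgol_order: int = 3
    savgol_window: int = 7
    fps: float = 30.0
    alpha_bits: float = 4.0
    beta: float = 200.0
    restarts: int = 100
    m_max: int = 10
    seed: int | None = None
    estimator: str = "exact"
    K: int = 100_000

    def __post_init__(self) -> None:
        if self.half_width_seconds <= 0:
            raise ValueError("half_width_seconds must be positive")
        if self.savgol_window % 2 == 0 or self.savgol_window < 3:
            raise ValueError("savgol_window must be odd and >= 3")
        if self.savgol_order >= self.savgol_window:
            raise ValueError("savgol_order must be below savgol_window")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.restarts < 1 or self.m_max < 2:
            raise ValueError("restarts >= 1 and m_max >= 2 required")
        if self.estimator not in ("exact", "mc"):
            raise ValueError("estimator must be 'exact' or 'mc'")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        import json

        return cls(**json.loads(Path(path).read_text()))


def read_tracks(path: str | Path, fps: float) -> TrackTable:
    """Read and canonicalize a (frame, id, x, y) delimited table.

    Rows are sorted by (frame, id); duplicate (frame, id) pairs are an
    error; original ids are mapped to 0..n-1 (mapping retained).
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"track table missing column(s): {', '.join(missing)}")
    dup = frame.duplicated(subset=["frame", "id"])
    if dup.any():
        first = frame.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (frame, id) pair: ({first['frame']}, {first['id']})"
        )
    originals = sorted(frame["id"].unique().tolist())
    mapping = {orig: k for k, orig in enumerate(originals)}
    out = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["id"] = out["id"].map(mapping)
    out = out.sort_values(["frame", "id"]).reset_index(drop=True)
    out["frame"] = out["frame"].astype(int)
    return TrackTable(data=out, fps=float(fps), id_mapping=mapping)


def savgol_velocities(
    tracks: TrackTable,
    order: int = 3,
    window_frames: int = 7,
    fps: float | None = None,
) -> pd.DataFrame:
    """Velocity series per individual via a Savitzky–Golay derivative.

    The smoothed first derivative is scaled by the frame rate (frames
    are one sample apart), computed per maximal contiguous run of each
    id.  Edge policy: only interior derivatives are kept — the first and
    last ``window_frames // 2`` frames of every run are dropped, rather
    than relying on polynomial extrapolation at the boundaries.
    Individuals without any run of at least ``window_frames`` contiguous
    frames are dropped with a warning.

    Returns a tidy DataFrame (frame, id, x, y, vx, vy).
    """
    fps = tracks.fps if fps is None else float(fps)
    half = window_frames // 2
    rows = []
    for ident, grp in tracks.data.groupby("id"):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        breaks = np.flatnonzero(np.diff(frames) != 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks + 1, [frames.size]])
        kept_any = False
        for lo, hi in zip(run_starts, run_ends):
            if hi - lo < window_frames:
                continue
            kept_any = True
            seg = grp.iloc[lo:hi]
            vx = savgol_filter(
                seg["x"].to_numpy(), window_frames, order, deriv=1, delta=1.0 / fps
            )
            vy = savgol_filter(
                seg["y"].to_numpy(), window_frames, order, deriv=1, delta=1.0 / fps
            )
            interior = slice(half, (hi - lo) - half)
            rows.append(
                pd.DataFrame(
                    {
                        "frame": seg["frame"].to_numpy()[interior],
                        "id": ident,
                        "x": seg["x"].to_numpy()[interior],
                        "y": seg["y"].to_numpy()[interior],
                        "vx": vx[interior],
                        "vy": vy[interior],
                    }
                )
            )
        if not kept_any:
            warnings.warn(
                f"individual {ident} has no contiguous run of "
                f">= {window_frames} frames; dropped",
                stacklevel=2,
            )
    if not rows:
        raise ValueError("no individual has enough contiguous frames")
    return pd.concat(rows, ignore_index=True).sort_values(
        ["frame", "id"], ignore_index=True
    )


def window_observations(
    velocities: pd.DataFrame,
    t_center: float,
    half_width_seconds: float = 15.0,
    fps: float = 30.0,
) -> ObservationMatrix:
    """Velocity observation matrix for a closed window of ±half-width.

    The window covers frames [round(t_center*fps) - H, ... + H] with
    H = round(half_width_seconds * fps), i.e. T = 2H + 1 samples.
    Individuals with any missing frame inside the window are excluded
    (no interpolation), with a warning.  Elements are (vx, vy) pairs.
    """
    center_frame = int(round(t_center * fps))
    H = int(round(half_width_seconds * fps))
    lo, hi = center_frame - H, center_frame + H
    present = velocities[
        (velocities["frame"] >= lo) & (velocities["frame"] <= hi)
    ]
    if lo < velocities["frame"].min() or hi > velocities["frame"].max():
        raise ValueError(
            f"window [{lo}, {hi}] extends past the recording "
            f"[{velocities['frame'].min()}, {velocities['frame'].max()}]"
        )
    T = 2 * H + 1
    kept, dropped = [], []
    for ident, grp in present.groupby("id"):
        if grp["frame"].nunique() == T:
            kept.append(int(ident))
        else:
            dropped.append(int(ident))
    if dropped:
        warnings.warn(
            f"individuals with gaps in window [{lo}, {hi}] excluded: "
            f"{dropped}",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no individual fully observed in the window")
    kept = sorted(kept)
    cols = np.empty((T, 2 * len(kept)))
    names = []
    for k, ident in enumerate(kept):
        grp = present[present["id"] == ident].sort_values("frame")
        cols[:, 2 * k] = grp["vx"].to_numpy()
        cols[:, 2 * k + 1] = grp["vy"].to_numpy()
        names.extend([f"vx{ident}", f"vy{ident}"])
    element_map = [[2 * k, 2 * k + 1] for k in range(len(kept))]
    return ObservationMatrix(cols, element_map, column_names=names)
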