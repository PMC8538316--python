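"""Chewing-signal generation from landmark tracks.

One chew is one up-down mandible cycle.  Per frame, the Euclidean distance
from each of the 11 jawline points (x_p, y_p) to the face box's upper-left
corner (u, v) is averaged:

    ED = (1/11) * sum_p sqrt((x_p - u)^2 + (y_p - v)^2)

and the per-frame averages, taken in frame order, form the chewing signal.
The reference corner is re-read from each frame's own face box, which tracks
the face, so whole-head translation cancels exactly.  Units are pixels; no
physical calibration is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingSampleError, UnusableTrackError
from .landmarks import LandmarkFrame, LandmarkTrack

__all__ = ["ChewSignal", "mean_jaw_distance", "build_chew_signal", "read_signal_csv", "write_signal_csv"]


@dataclass
class ChewSignal:
    """Uniformly sampled 1-D series of mean jaw-to-reference distances.

    ``missing_mask`` flags samples that were filled in for invalid frames
    rather than measured.
    """

    values: np.ndarray
    fps: float
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("signal values must be 1-D")
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be positive, got {self.fps}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise InvalidInputError("missing_mask must match values in length")
        if not np.isfinite(self.values[~self.missing_mask]).all():
            raise InvalidInputError("measured samples must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.values) / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps

    def with_values(self, values: np.ndarray, fps: float | None = None) -> "ChewSignal":
        """Same-metadata copy with new sample values (e.g. after filtering)."""
        n = len(values)
        mask = self.missing_mask if n == len(self) else np.zeros(n, dtype=bool)
        return ChewSignal(values=np.asarray(values, float), fps=fps or self.fps, missing_mask=mask)


def mean_jaw_distance(frame: LandmarkFrame) -> float:
    """Mean Euclidean distance of the 11 jaw points to the reference corner (u, v)."""
    if not frame.valid:
        raise MissingSampleError(f"frame {frame.frame_index} carries no valid detection")
    u, v = frame.face.reference_point
    d = np.hypot(frame.jaw_points[:, 0] - u, frame.jaw_points[:, 1] - v)
    return float(d.mean())


def build_chew_signal(track: LandmarkTrack, gap_policy: str = "linear") -> ChewSignal:
    """One ED sample per frame, with detector dropouts filled per ``gap_policy``.

    Policies: ``linear`` interpolates across gaps (edges extend the nearest
    measured value); ``hold`` repeats the last measured value.  Filled
    samples are flagged in ``missing_mask``.  Tracks with more than half
    their frames invalid are rejected as unusable.
    """
    if len(track) == 0:
        raise InvalidInputError("empty track")
    if gap_policy not in ("linear", "hold"):
        raise InvalidInputError(f"unknown gap policy {gap_policy!r}")
    n = len(track)
    valid = np.array([f.valid for f in track.frames])
    if valid.sum() < 0.5 * n:
        raise UnusableTrackError(f"only {valid.sum()}/{n} frames valid; need at least 50%")
    values = np.full(n, np.nan)
    for i, f in enumerate(track.frames):
        if f.valid:
            values[i] = mean_jaw_distance(f)
    missing = ~valid
    if missing.any():
        idx = np.arange(n)
        if gap_policy == "linear":
            values[missing] = np.interp(idx[missing], idx[valid], values[valid])
        else:  # hold-last; leading gap takes the first measured value
            fill = np.maximum.accumulate(np.where(valid, idx, -1))
            first_valid = idx[valid][0]
            fill[fill < 0] = first_valid
            values[missing] = values[fill[missing]]
    return ChewSignal(values=values, fps=track.fps, missing_mask=missing)


def write_signal_csv(sig: ChewSignal, path) -> None:
    """Columns: t_seconds, ed_pixels, missing."""
    pd.DataFrame(
        {"t_seconds": sig.times, "ed_pixels": sig.values, "missing": sig.missing_mask.astype(int)}
    ).to_csv(path, index=False)


def read_signal_csv(path) -> ChewSignal:
    df = pd.read_csv(path)
    t = df["t_seconds"].to_numpy()
    if len(t) < 2:
        raise InvalidInputError("signal CSV needs at least two samples to infer fps")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError("signal CSV is not uniformly sampled")
    return ChewSignal(
        values=df["ed_pixels"].to_numpy(),
        fps=round(1.0 / dt[0], 9),  # undo decimal round-trip jitter in t_seconds
        missing_mask=df["missing"].to_numpy().astype(bool),
    )
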