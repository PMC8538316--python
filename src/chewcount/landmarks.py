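"""Face boxes, jawline landmarks, and per-frame tracking.

The pipeline needs, per video frame, a face bounding box (whose upper-left
corner is the motion reference point) and 11 jawline/chin landmarks.  The
detection models themselves are pluggable backends satisfying two small
protocols; this module owns the orchestration, the 11-point jaw selection,
and the CSV interchange format between the image side and the signal side.

Backend contracts
-----------------
Face detector:  ``detect(gray: ndarray) -> list[(Rect, confidence)]``
Landmark model: ``locate(gray: ndarray, face: FaceBox) -> ndarray (N, 2)``
                plus a ``jaw_indices`` attribute (or an explicit mapping
                argument) selecting the 11 chin/jawline points out of the
                backend's full point set.

For the common 68-point annotation scheme the jawline is points 0-16; the
11 central chin/jaw points used here are indices 3..13.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import BackendError, ConfigurationError, InvalidInputError
from .haar import Rect

__all__ = [
    "FaceBox",
    "LandmarkFrame",
    "LandmarkTrack",
    "JAW_INDICES_68",
    "detect_face",
    "detect_landmarks",
    "track_video",
    "read_track_csv",
    "write_track_csv",
]

N_JAW_POINTS = 11

#: 11 central chin/jawline indices within a standard 68-point annotation.
JAW_INDICES_68: tuple[int, ...] = tuple(range(3, 14))


@dataclass(frozen=True)
class FaceBox:
    """Face bounding box; (x, y) is the upper-left corner, the reference point (u, v)."""

    x: float
    y: float
    w: float
    h: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise InvalidInputError(f"face box extents must be positive, got w={self.w} h={self.h}")

    @property
    def reference_point(self) -> tuple[float, float]:
        """(u, v): the corner every jaw-point distance is measured from."""
        return (self.x, self.y)


@dataclass(frozen=True)
class LandmarkFrame:
    """One frame's detections: face box plus 11 jaw points, or an invalid marker."""

    frame_index: int
    face: FaceBox | None
    jaw_points: np.ndarray | None  # (11, 2) float array, columns (x, y)
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if self.face is None or self.jaw_points is None:
                raise InvalidInputError("valid frame requires a face box and jaw points")
            pts = np.asarray(self.jaw_points, dtype=float)
            if pts.shape != (N_JAW_POINTS, 2):
                raise InvalidInputError(f"expected ({N_JAW_POINTS}, 2) jaw points, got {pts.shape}")
            if not np.isfinite(pts).all():
                raise InvalidInputError("jaw points must be finite")
            object.__setattr__(self, "jaw_points", pts)

    @classmethod
    def invalid(cls, frame_index: int) -> "LandmarkFrame":
        return cls(frame_index=frame_index, face=None, jaw_points=None, valid=False)


@dataclass
class LandmarkTrack:
    """Ordered per-frame landmark detections at a fixed sampling rate."""

    frames: list[LandmarkFrame]
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be positive, got {self.fps}")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InvalidInputError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_valid(self) -> int:
        return sum(f.valid for f in self.frames)


@runtime_checkable
class FaceDetectorBackend(Protocol):
    def detect(self, gray: np.ndarray) -> list[tuple[Rect, float]]: ...


@runtime_checkable
class LandmarkBackend(Protocol):
    def locate(self, gray: np.ndarray, face: FaceBox) -> np.ndarray: ...


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to single-channel luminance; pass gray through."""
    a = np.asarray(img)
    if a.ndim == 2:
        return a
    if a.ndim == 3 and a.shape[2] in (3, 4):
        return a[..., :3] @ np.array([0.299, 0.587, 0.114])
    raise InvalidInputError(f"cannot interpret image of shape {a.shape}")


def detect_face(img: np.ndarray, backend: FaceDetectorBackend, frame_index: int = 0) -> FaceBox | None:
    """Run the face detector on one frame; keep the single most confident box.

    Frames are converted to grayscale before detection.  Returns ``None``
    when the backend reports no face (single-subject policy: multiple
    candidates reduce to the highest-confidence one).
    """
    gray = to_grayscale(img)
    try:
        candidates = backend.detect(gray)
    except Exception as exc:  # noqa: BLE001 - backend contract: any failure flags the frame
        raise BackendError(f"face detector failed on frame {frame_index}: {exc}") from exc
    if not candidates:
        return None
    best, _score = max(candidates, key=lambda rc: rc[1])
    return FaceBox(x=best.x, y=best.y, w=best.w, h=best.h, frame_index=frame_index)


def detect_landmarks(
    img: np.ndarray,
    face: FaceBox,
    backend: LandmarkBackend,
    jaw_indices: Sequence[int] | None = None,
) -> LandmarkFrame:
    """Map a backend's full landmark set to the 11 chin/jawline points.

    ``jaw_indices`` overrides the backend's own ``jaw_indices`` attribute.
    A backend returning too few points marks the frame invalid rather than
    raising, so gaps stay visible to the signal stage.
    """
    indices = tuple(jaw_indices) if jaw_indices is not None else getattr(backend, "jaw_indices", None)
    if indices is None:
        raise ConfigurationError("no jaw-index mapping configured for landmark backend")
    if len(indices) != N_JAW_POINTS:
        raise ConfigurationError(f"jaw-index mapping must select {N_JAW_POINTS} points, got {len(indices)}")
    try:
        pts = np.asarray(backend.locate(to_grayscale(img), face), dtype=float)
    except Exception:  # noqa: BLE001
        return LandmarkFrame.invalid(face.frame_index)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] <= max(indices):
        return LandmarkFrame.invalid(face.frame_index)
    return LandmarkFrame(frame_index=face.frame_index, face=face, jaw_points=pts[list(indices)])


_FRAME_FILE = re.compile(r".*?(\d+)\.(png|jpg|jpeg|bmp|tif|tiff)$", re.IGNORECASE)


def _iter_frame_dir(path: Path) -> Iterable[np.ndarray]:
    import imageio.v3 as iio

    files = sorted(
        (p for p in path.iterdir() if _FRAME_FILE.match(p.name)),
        key=lambda p: int(_FRAME_FILE.match(p.name).group(1)),
    )
    if not files:
        raise InvalidInputError(f"no numbered image frames found in {path}")
    for p in files:
        yield iio.imread(p)


def track_video(
    video: str | Path | Iterable[np.ndarray],
    face_backend: FaceDetectorBackend,
    landmark_backend: LandmarkBackend,
    fps: float,
    jaw_indices: Sequence[int] | None = None,
) -> LandmarkTrack:
    """Run detection over a frame source and assemble a LandmarkTrack.

    ``video`` is either a directory of numbered images or any iterable of
    frame arrays.  Detection failures flag frames invalid; nothing is
    dropped, so the signal stage controls gap handling.  Deterministic:
    identical frames yield identical tracks.
    """
    if isinstance(video, (str, Path)):
        path = Path(video)
        if not path.is_dir():
            raise InvalidInputError(
                f"{path} is not a frame directory; decode containers upstream or supply frames"
            )
        frames_iter: Iterable[np.ndarray] = _iter_frame_dir(path)
    else:
        frames_iter = video

    frames: list[LandmarkFrame] = []
    for i, img in enumerate(frames_iter):
        try:
            face = detect_face(img, face_backend, frame_index=i)
        except BackendError:
            face = None
        if face is None:
            frames.append(LandmarkFrame.invalid(i))
            continue
        frames.append(detect_landmarks(img, face, landmark_backend, jaw_indices))
    if not frames:
        raise InvalidInputError("frame source yielded no frames")
    return LandmarkTrack(frames=frames, fps=fps)


# ---------------------------------------------------------------------------
# CSV interchange: frame, u, v, w, h, x1, y1, ..., x11, y11, valid
# ---------------------------------------------------------------------------

_POINT_COLS = [c for p in range(1, N_JAW_POINTS + 1) for c in (f"x{p}", f"y{p}")]
TRACK_COLUMNS = ["frame", "u", "v", "w", "h", *_POINT_COLS, "valid"]


def write_track_csv(track: LandmarkTrack, path: str | Path) -> None:
    """Write the track in the interchange format (fps recorded in a header comment)."""
    rows = []
    for f in track.frames:
        if f.valid:
            rows.append([f.frame_index, f.face.x, f.face.y, f.face.w, f.face.h,
                         *f.jaw_points.ravel(), 1])
        else:
            rows.append([f.frame_index, *([np.nan] * (4 + 2 * N_JAW_POINTS)), 0])
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# fps={track.fps}\n")
        df.to_csv(fh, index=False)


def read_track_csv(path: str | Path, fps: float | None = None) -> LandmarkTrack:
    """Read a track CSV; ``fps`` overrides the header comment when given."""
    with open(path) as fh:
        first = fh.readline()
        header_fps = None
        if first.startswith("#"):
            m = re.search(r"fps=([\d.]+)", first)
            if m:
                header_fps = float(m.group(1))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    rate = fps if fps is not None else header_fps
    if rate is None:
        raise ConfigurationError(f"{path} has no fps header; pass fps explicitly")
    frames = []
    for row in df.itertuples(index=False):
        if int(row.valid):
            face = FaceBox(x=row.u, y=row.v, w=row.w, h=row.h, frame_index=int(row.frame))
            pts = np.array([[getattr(row, f"x{p}"), getattr(row, f"y{p}")]
                            for p in range(1, N_JAW_POINTS + 1)])
            frames.append(LandmarkFrame(frame_index=int(row.frame), face=face, jaw_points=pts))
        else:
            frames.append(LandmarkFrame.invalid(int(row.frame)))
    return LandmarkTrack(frames=frames, fps=rate)


def translate_track(track: LandmarkTrack, dx: float, dy: float) -> LandmarkTrack:
    """Shift every face box and jaw point by (dx, dy); used to test invariances."""
    frames = []
    for f in track.frames:
        if not f.valid:
            frames.append(f)
            continue
        face = replace(f.face, x=f.face.x + dx, y=f.face.y + dy)
        frames.append(LandmarkFrame(f.frame_index, face, f.jaw_points + np.array([dx, dy])))
    return LandmarkTrack(frames=frames, fps=track.fps)
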