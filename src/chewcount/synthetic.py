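"""Ground-truthed synthetic chewing data.

The study population this package targets — one-minute clips of single
subjects chewing at slow/normal/fast speeds, filmed at 30 fps — is emulated
here so every stage is testable end to end.  The generator plants:

* quasi-periodic mandible oscillation (per-cycle jittered rate and
  amplitude, asymmetric raised-cosine cycles: faster close than open),
* occasional bite excursions (a several-fold larger cycle followed by a
  short pause),
* swallow pauses with no oscillation,
* additive white detector noise and slow head-drift baseline wander,

and records the exact ground truth (chew count, per-chew peak times, bite
times, pause intervals).  Landmark tracks are built so that the chewing
signal recovered by :func:`chewcount.signal.build_chew_signal` equals the
planted distance series to rounding error, with whole-head translation
noise that cancels by construction.

All randomness flows from a single integer seed through NumPy's default
PCG64 generator, so outputs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidInputError
from .haar import Rect, rects_cover
from .landmarks import N_JAW_POINTS, FaceBox, LandmarkFrame, LandmarkTrack
from .signal import ChewSignal

__all__ = [
    "ChewScenario",
    "GroundTruth",
    "generate_chew_signal",
    "generate_landmark_track",
    "generate_test_images",
    "make_face_image",
    "ToyHaarFaceDetector",
    "ReplayFaceDetector",
    "ReplayLandmarkBackend",
    "scenario_for_speed",
    "SPEED_RATE_RANGES",
]

#: Chew-rate ranges (Hz) per speed label, spanning the 0.4-2.3 Hz band
#: observed across chewing speeds.
SPEED_RATE_RANGES: dict[str, tuple[float, float]] = {
    "slow": (0.6, 0.9),
    "normal": (1.0, 2.0),
    "fast": (2.0, 2.3),
}


@dataclass(frozen=True)
class ChewScenario:
    """Parameters of one synthetic clip.  Defaults model a one-minute 30 fps
    recording with detector noise at 15% of the chew amplitude and two bites."""

    duration_s: float = 60.0
    fps: float = 30.0
    chew_rate_hz: float = 1.5
    chew_amplitude_px: float = 6.0
    rate_jitter_frac: float = 0.05
    amplitude_jitter_frac: float = 0.15
    asym_peak_frac: float = 0.4          # peak position within a cycle (close faster than open)
    n_bites: int = 2
    bite_amplitude_mult: float = 3.0
    bite_duration_s: float = 1.2
    bite_pause_s: float = 1.0
    n_swallow_pauses: int = 1
    swallow_pause_s: float = 1.0
    noise_sd_frac: float = 0.15          # white noise SD as a fraction of chew amplitude
    drift_amplitude_px: float = 1.5      # slow head-motion baseline wander
    drift_period_s: float = 20.0
    baseline_px: float = 40.0
    dropout_rate: float = 0.0            # per-frame probability of a failed detection
    head_motion_px: float = 0.0          # RMS whole-head translation (cancels in the signal)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.chew_rate_hz < self.fps / 2:
            raise InvalidInputError("chew rate must lie in (0, fps/2)")
        if self.chew_amplitude_px <= 0 or self.duration_s <= 0 or self.fps <= 0:
            raise InvalidInputError("duration, fps and amplitude must be positive")
        if not 0 < self.asym_peak_frac < 1:
            raise InvalidInputError("asym_peak_frac must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Exact planted events of one synthetic clip."""

    true_chew_count: int
    chew_peak_times: list[float] = field(default_factory=list)
    bite_times: list[float] = field(default_factory=list)
    pause_intervals: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _cycle_shape(u: np.ndarray, peak_frac: float) -> np.ndarray:
    """Asymmetric raised-cosine bump on [0, 1): 0 -> 1 at ``peak_frac`` -> 0."""
    out = np.empty_like(u)
    rising = u < peak_frac
    out[rising] = 0.5 * (1 - np.cos(np.pi * u[rising] / peak_frac))
    out[~rising] = 0.5 * (1 + np.cos(np.pi * (u[~rising] - peak_frac) / (1 - peak_frac)))
    return out


def generate_chew_signal(scn: ChewScenario) -> tuple[ChewSignal, GroundTruth]:
    """Synthesize one clip's chewing signal plus its exact ground truth.

    The clip is laid out event by event: chew cycles follow one another at
    the (jittered) chew rate; bite excursions and swallow pauses are planted
    at pre-drawn times.  A cycle only counts as a chew when it completes
    within the record.
    """
    rng = np.random.default_rng(scn.seed)
    n = int(round(scn.duration_s * scn.fps))
    t_grid = np.arange(n) / scn.fps
    values = np.zeros(n)

    # Pre-draw event times away from the clip edges, enforcing separation so
    # bite + pause blocks cannot overlap.
    margin = 0.08 * scn.duration_s
    n_events = scn.n_bites + scn.n_swallow_pauses
    event_times: list[tuple[float, str]] = []
    if n_events:
        span = scn.duration_s - 2 * margin
        min_sep = scn.bite_duration_s + scn.bite_pause_s + 1.0
        for _ in range(200):
            times = np.sort(rng.uniform(margin, margin + span, n_events))
            if n_events == 1 or np.diff(times).min() >= min_sep:
                break
        kinds = ["bite"] * scn.n_bites + ["pause"] * scn.n_swallow_pauses
        rng.shuffle(kinds)
        event_times = list(zip(times, kinds))

    def add_bump(start: float, dur: float, amp: float) -> float:
        """Deposit one raised-cosine cycle; returns the exact peak time."""
        i0 = int(np.ceil(start * scn.fps - 1e-9))
        i1 = min(n, int(np.ceil((start + dur) * scn.fps - 1e-9)))
        if i1 > i0:
            u = (t_grid[i0:i1] - start) / dur
            values[i0:i1] += amp * _cycle_shape(u, scn.asym_peak_frac)
        return start + scn.asym_peak_frac * dur

    truth = GroundTruth(true_chew_count=0)
    t = 0.0
    ev = 0
    eps = 1e-9
    while True:
        if ev < len(event_times) and t >= event_times[ev][0] - eps:
            when, kind = event_times[ev]
            ev += 1
            if kind == "bite":
                if t + scn.bite_duration_s > scn.duration_s + eps:
                    continue
                peak = add_bump(t, scn.bite_duration_s,
                                scn.bite_amplitude_mult * scn.chew_amplitude_px)
                truth.bite_times.append(peak)
                truth.pause_intervals.append((t + scn.bite_duration_s,
                                              min(t + scn.bite_duration_s + scn.bite_pause_s,
                                                  scn.duration_s)))
                t += scn.bite_duration_s + scn.bite_pause_s
            else:
                truth.pause_intervals.append((t, min(t + scn.swallow_pause_s, scn.duration_s)))
                t += scn.swallow_pause_s
            continue
        rate = scn.chew_rate_hz * (1 + scn.rate_jitter_frac * rng.uniform(-1, 1))
        cycle = 1.0 / rate
        if t + cycle > scn.duration_s + eps:
            break
        amp = scn.chew_amplitude_px * (1 + scn.amplitude_jitter_frac * rng.uniform(-1, 1))
        truth.chew_peak_times.append(add_bump(t, cycle, amp))
        truth.true_chew_count += 1
        t += cycle

    drift_phase = rng.uniform(0, 2 * np.pi)
    values += scn.baseline_px
    if scn.drift_amplitude_px > 0:
        values += scn.drift_amplitude_px * np.sin(2 * np.pi * t_grid / scn.drift_period_s + drift_phase)
    if scn.noise_sd_frac > 0:
        values += rng.normal(0.0, scn.noise_sd_frac * scn.chew_amplitude_px, n)

    return ChewSignal(values=values, fps=scn.fps), truth


def scenario_for_speed(speed: str, seed: int, **overrides) -> ChewScenario:
    """Scenario with a chew rate drawn uniformly from the speed's rate band.

    The draw uses its own generator (seeded from ``seed``) so the clip
    synthesis downstream sees an independent stream.
    """
    lo, hi = SPEED_RATE_RANGES[speed]
    rate = float(np.random.default_rng((seed, 777)).uniform(lo, hi))
    return ChewScenario(chew_rate_hz=rate, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Landmark-track synthesis
# ---------------------------------------------------------------------------

def generate_landmark_track(scn: ChewScenario) -> tuple[LandmarkTrack, GroundTruth]:
    """Geometric embedding of the chewing signal as an 11-point jaw track.

    Jaw point p sits at distance ``c_p * s(t)`` from the face-box corner
    along a fixed ray, with the per-point factors c_p normalised to mean 1 —
    so the mean jaw distance reproduces the planted series s(t) exactly.
    Whole-head translation (shared by box and points) and per-frame dropout
    are applied on top.
    """
    sig, truth = generate_chew_signal(scn)
    rng = np.random.default_rng((scn.seed, 1234))
    n = len(sig)

    c = rng.uniform(0.9, 1.1, N_JAW_POINTS)
    c /= c.mean()
    theta = np.deg2rad(np.linspace(50.0, 130.0, N_JAW_POINTS))
    ray = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # y grows downward

    if scn.head_motion_px > 0:
        steps = rng.normal(0.0, 1.0, (n, 2))
        walk = np.cumsum(steps, axis=0)
        k = max(3, int(scn.fps) | 1)
        kernel = np.hanning(k)
        kernel /= kernel.sum()
        walk = np.stack([np.convolve(walk[:, j], kernel, mode="same") for j in range(2)], axis=1)
        rms = np.sqrt((walk**2).mean())
        head = walk * (scn.head_motion_px / max(rms, 1e-12))
    else:
        head = np.zeros((n, 2))

    dropout = rng.uniform(size=n) < scn.dropout_rate if scn.dropout_rate > 0 else np.zeros(n, bool)

    u0, v0, box_w, box_h = 100.0, 80.0, 160.0, 160.0
    frames = []
    for i in range(n):
        if dropout[i]:
            frames.append(LandmarkFrame.invalid(i))
            continue
        u, v = u0 + head[i, 0], v0 + head[i, 1]
        face = FaceBox(x=u, y=v, w=box_w, h=box_h, frame_index=i)
        pts = np.array([u, v]) + (c[:, None] * sig.values[i]) * ray
        frames.append(LandmarkFrame(frame_index=i, face=face, jaw_points=pts))
    return LandmarkTrack(frames=frames, fps=scn.fps), truth


# ---------------------------------------------------------------------------
# Toy images and detection backends for exercising the image-side plumbing
# ---------------------------------------------------------------------------

def generate_test_images(n: int = 5, shape: tuple[int, int] = (8, 8), seed: int = 0,
                         max_value: int = 255) -> list[np.ndarray]:
    """Deterministic small random integer images for integral/Haar oracles."""
    rng = np.random.default_rng(seed)
    return [rng.integers(0, max_value + 1, size=shape).astype(np.int64) for _ in range(n)]


def make_face_image(size: int = 48, face: Rect | None = None, seed: int = 0,
                    noise_sd: float = 4.0) -> tuple[np.ndarray, Rect]:
    """Light background with one dark square 'face' patch; returns (image, box)."""
    rng = np.random.default_rng(seed)
    if face is None:
        fw = size // 3
        x = int(rng.integers(2, size - fw - 2))
        y = int(rng.integers(2, size - fw - 2))
        face = Rect(x, y, fw, fw)
    img = np.full((size, size), 200.0)
    img[face.y:face.y + face.h, face.x:face.x + face.w] = 80.0
    img += rng.normal(0, noise_sd, img.shape)
    return np.clip(img, 0, 255), face


class ToyHaarFaceDetector:
    """Single-scale template detector built on the integral-image layer.

    Scores each window by the ring-minus-centre Haar contrast (a dark patch
    on a light surround), normalised per pixel; windows above ``threshold``
    are candidate faces.  A testing stand-in for a trained cascade backend —
    it honours the same contract.
    """

    def __init__(self, face_size: int, threshold: float = 20.0, stride: int = 2):
        self.face_size = face_size
        self.threshold = threshold
        self.stride = stride

    def detect(self, gray: np.ndarray) -> list[tuple[Rect, float]]:
        from .haar import compute_integral_image, box_sum

        s = self.face_size
        pad = max(2, s // 4)
        win = s + 2 * pad
        h, w = gray.shape
        if h < win or w < win:
            return []
        ii = compute_integral_image(gray)
        best: tuple[Rect, float] | None = None
        for y in range(0, h - win + 1, self.stride):
            for x in range(0, w - win + 1, self.stride):
                outer = box_sum(ii, Rect(x, y, win, win))
                inner = box_sum(ii, Rect(x + pad, y + pad, s, s))
                ring_area = win * win - s * s
                score = (outer - inner) / ring_area - inner / (s * s)
                if score > self.threshold and (best is None or score > best[1]):
                    best = (Rect(x + pad, y + pad, s, s), score)
        return [best] if best else []


class ReplayFaceDetector:
    """Face 'detector' that replays the boxes of a stored track (mock backend)."""

    def __init__(self, track: LandmarkTrack):
        self._boxes = {f.frame_index: f.face for f in track.frames if f.valid}
        self._cursor = [f.frame_index for f in track.frames]
        self._i = 0

    def detect(self, gray: np.ndarray) -> list[tuple[Rect, float]]:
        idx = self._cursor[self._i]
        self._i += 1
        face = self._boxes.get(idx)
        if face is None:
            return []
        return [(Rect(int(round(face.x)), int(round(face.y)),
                      int(round(face.w)), int(round(face.h))), 1.0)]


class ReplayLandmarkBackend:
    """Landmark provider replaying a stored track as a 68-point annotation.

    The 11 jaw points occupy the standard chin/jawline slots (indices 3-13);
    the other 57 slots are filled with placeholder points so index mapping is
    exercised for real.
    """

    jaw_indices = tuple(range(3, 14))

    def __init__(self, track: LandmarkTrack, n_points: int = 68):
        self._frames = {f.frame_index: f for f in track.frames}
        self.n_points = n_points

    def locate(self, gray: np.ndarray, face: FaceBox) -> np.ndarray:
        f = self._frames.get(face.frame_index)
        if f is None or not f.valid:
            raise RuntimeError(f"no stored landmarks for frame {face.frame_index}")
        pts = np.tile([face.x + face.w / 2, face.y + face.h / 2], (self.n_points, 1)).astype(float)
        pts[list(self.jaw_indices)] = f.jaw_points
        return pts
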