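"""Face/landmark acquisition: backend contracts, tracking, CSV interchange."""

import numpy as np
import pytest

from chewcount.errors import ConfigurationError, InvalidInputError
from chewcount.haar import Rect, rect_iou
from chewcount.landmarks import (JAW_INDICES_68, FaceBox, LandmarkFrame, LandmarkTrack,
                                 detect_face, detect_landmarks, read_track_csv, track_video,
                                 translate_track, write_track_csv)
from chewcount.signal import build_chew_signal
from chewcount.synthetic import (ChewScenario, ReplayFaceDetector, ReplayLandmarkBackend,
                                 ToyHaarFaceDetector, generate_landmark_track, make_face_image)


class StubDetector:
    def __init__(self, candidates):
        self.candidates = candidates

    def detect(self, gray):
        return self.candidates


class TestDetectFace:
    def test_blank_image_yields_none(self):
        img = np.full((48, 48), 128.0)
        assert detect_face(img, ToyHaarFaceDetector(face_size=16)) is None

    def test_planted_face_found_with_iou_above_half(self):
        for seed in range(5):
            img, true_box = make_face_image(size=48, seed=seed)
            got = detect_face(img, ToyHaarFaceDetector(face_size=true_box.w))
            assert got is not None
            assert rect_iou(Rect(int(got.x), int(got.y), int(got.w), int(got.h)), true_box) > 0.5

    def test_highest_confidence_candidate_wins(self):
        det = StubDetector([(Rect(0, 0, 4, 4), 0.3), (Rect(8, 8, 4, 4), 0.9)])
        got = detect_face(np.zeros((16, 16)), det)
        assert (got.x, got.y) == (8, 8)

    def test_rgb_frames_are_grayscaled_before_detection(self):
        img, true_box = make_face_image(size=48, seed=1)
        rgb = np.stack([img] * 3, axis=-1)
        got = detect_face(rgb, ToyHaarFaceDetector(face_size=true_box.w))
        assert got is not None


class TestDetectLandmarks:
    def _frame_backend(self):
        scn = ChewScenario(duration_s=2.0, noise_sd_frac=0.0, n_bites=0,
                           n_swallow_pauses=0, drift_amplitude_px=0.0, seed=3)
        track, _ = generate_landmark_track(scn)
        return track, ReplayLandmarkBackend(track)

    def test_68_point_backend_maps_to_11_jaw_points(self):
        track, backend = self._frame_backend()
        f0 = track.frames[0]
        out = detect_landmarks(np.zeros((8, 8)), f0.face, backend)
        assert out.valid and out.jaw_points.shape == (11, 2)
        np.testing.assert_allclose(out.jaw_points, f0.jaw_points)

    def test_missing_mapping_is_configuration_error(self):
        track, backend = self._frame_backend()
        del ReplayLandmarkBackend.jaw_indices  # simulate unconfigured backend
        try:
            with pytest.raises(ConfigurationError):
                detect_landmarks(np.zeros((8, 8)), track.frames[0].face, backend)
        finally:
            ReplayLandmarkBackend.jaw_indices = tuple(range(3, 14))

    def test_backend_failure_marks_frame_invalid(self):
        class Failing:
            jaw_indices = JAW_INDICES_68

            def locate(self, gray, face):
                raise RuntimeError("model unavailable")

        out = detect_landmarks(np.zeros((8, 8)), FaceBox(0, 0, 4, 4, frame_index=2), Failing())
        assert not out.valid and out.frame_index == 2

    def test_too_few_points_marks_frame_invalid(self):
        class Short:
            jaw_indices = JAW_INDICES_68

            def locate(self, gray, face):
                return np.zeros((5, 2))

        assert not detect_landmarks(np.zeros((8, 8)), FaceBox(0, 0, 4, 4), Short()).valid


class TestTrackVideo:
    def _replay_setup(self):
        scn = ChewScenario(duration_s=3.0, noise_sd_frac=0.0, n_bites=0,
                           n_swallow_pauses=0, drift_amplitude_px=0.0, seed=5)
        track, truth = generate_landmark_track(scn)
        frames = [np.zeros((8, 8))] * len(track)
        return track, frames, truth

    def test_replay_roundtrip_reproduces_coordinates(self):
        stored, frames, _ = self._replay_setup()
        out = track_video(frames, ReplayFaceDetector(stored), ReplayLandmarkBackend(stored),
                          fps=stored.fps)
        assert len(out) == len(stored)
        for a, b in zip(out.frames, stored.frames):
            np.testing.assert_allclose(a.jaw_points, b.jaw_points)
        np.testing.assert_allclose(build_chew_signal(out).values,
                                   build_chew_signal(stored).values)

    def test_tracking_is_deterministic(self):
        stored, frames, _ = self._replay_setup()
        runs = [track_video(frames, ReplayFaceDetector(stored), ReplayLandmarkBackend(stored),
                            fps=stored.fps) for _ in range(2)]
        for a, b in zip(runs[0].frames, runs[1].frames):
            assert a.valid == b.valid
            if a.valid:
                np.testing.assert_array_equal(a.jaw_points, b.jaw_points)

    def test_undetected_frames_flagged_not_dropped(self):
        stored, frames, _ = self._replay_setup()

        class SometimesBlind(ReplayFaceDetector):
            def detect(self, gray):
                out = super().detect(gray)
                return [] if (self._i % 5 == 0) else out

        out = track_video(frames, SometimesBlind(stored), ReplayLandmarkBackend(stored),
                          fps=stored.fps)
        assert len(out) == len(stored)
        assert 0 < len(out) - out.n_valid < len(out)

    def test_empty_source_rejected(self):
        with pytest.raises(InvalidInputError):
            track_video([], StubDetector([]), ReplayLandmarkBackend(
                generate_landmark_track(ChewScenario(duration_s=1.0, seed=0))[0]), fps=30)


class TestTrackCsv:
    def test_roundtrip_preserves_track(self, tmp_path):
        scn = ChewScenario(duration_s=2.0, dropout_rate=0.2, seed=9)
        track, _ = generate_landmark_track(scn)
        path = tmp_path / "track.csv"
        write_track_csv(track, path)
        back = read_track_csv(path)
        assert back.fps == track.fps and len(back) == len(track)
        for a, b in zip(back.frames, track.frames):
            assert a.valid == b.valid
            if a.valid:
                np.testing.assert_allclose(a.jaw_points, b.jaw_points)
                assert a.face.reference_point == pytest.approx(b.face.reference_point)

    def test_fps_override_and_missing_header(self, tmp_path):
        track, _ = generate_landmark_track(ChewScenario(duration_s=1.0, seed=2))
        path = tmp_path / "t.csv"
        write_track_csv(track, path)
        assert read_track_csv(path, fps=25.0).fps == 25.0
        # strip header comment
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[1:]) + "\n")
        with pytest.raises(ConfigurationError):
            read_track_csv(path)


def test_frame_indices_must_strictly_increase():
    f = LandmarkFrame.invalid(0)
    with pytest.raises(InvalidInputError):
        LandmarkTrack(frames=[f, f], fps=30.0)


def test_translate_track_moves_box_and_points_together():
    track, _ = generate_landmark_track(ChewScenario(duration_s=1.0, seed=4))
    moved = translate_track(track, 11.0, -3.0)
    f0, g0 = track.frames[0], moved.frames[0]
    np.testing.assert_allclose(g0.jaw_points - f0.jaw_points, [[11.0, -3.0]] * 11)
    assert g0.face.x - f0.face.x == pytest.approx(11.0)
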