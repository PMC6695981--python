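import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headbcg import errors, tracking
from headbcg.tracking import FrameSequence, derive_subrois, detect_face, extract_points, track

from conftest import make_patch_video


class TestDeriveSubrois:
    def test_unit_square_forehead(self):
        rois = derive_subrois((0, 0, 100, 100))
        assert rois.forehead_box == (25, 0, 50, 20)

    def test_unit_square_nose(self):
        rois = derive_subrois((0, 0, 100, 100))
        assert rois.nose_box == (25, 38, 50, 25)

    def test_offset_box(self):
        rois = derive_subrois((10, 20, 200, 300))
        assert rois.forehead_box == (60, 20, 100, 60)

    def test_degenerate(self):
        with pytest.raises(errors.DegenerateBox):
            derive_subrois((0, 0, 0, 10))
        with pytest.raises(errors.DegenerateBox):
            derive_subrois((0, 0, 10, 1))  # 0.2 * 1 rounds to 0

    @given(
        x=st.integers(0, 50), y=st.integers(0, 50),
        w=st.integers(20, 200), h=st.integers(20, 200),
        c=st.integers(2, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance_before_rounding(self, x, y, w, h, c):
        a = derive_subrois((x, y, w, h))
        b = derive_subrois((c * x, c * y, c * w, c * h))
        # fractions applied before rounding: scaled box within rounding slack
        for small, big in ((a.forehead_box, b.forehead_box), (a.nose_box, b.nose_box)):
            for u, v in zip(small, big):
                assert abs(v - c * u) <= c  # one rounding unit, scaled

    def test_subboxes_inside_face(self):
        rois = derive_subrois((5, 7, 101, 93))
        fx, fy, fw, fh = rois.face_box
        for x, y, w, h in (rois.forehead_box, rois.nose_box):
            assert fx <= x and x + w <= fx + fw + 1
            assert fy <= y and y + h <= fy + fh + 1


class TestDetectFace:
    def test_astronaut_face(self):
        from skimage import data

        box = detect_face(data.astronaut())
        x, y, w, h = box
        cx, cy = x + w / 2, y + h / 2
        # the photo's face occupies roughly x in [170, 290], y in [50, 210]
        assert 150 < cx < 300
        assert 40 < cy < 220
        assert w > 40 and h > 40

    def test_blank_frame(self):
        with pytest.raises(errors.NoFaceFound):
            detect_face(np.full((120, 160), 0.5))

    def test_manual_override(self):
        frame = np.zeros((10, 10))
        assert detect_face(frame, manual_box=(1, 2, 3, 4)) == (1, 2, 3, 4)


class TestExtractPoints:
    def _checker_frame(self):
        frame = np.full((120, 160), 0.5)
        yy, xx = np.mgrid[0:120, 0:160]
        frame[(yy // 4 + xx // 4) % 2 == 0] = 1.0
        return frame

    def test_checkerboard_has_points(self):
        frame = self._checker_frame()
        rois = derive_subrois((20, 10, 100, 100))
        pts = extract_points(frame, rois)
        fx, fy, fw, fh = rois.forehead_box
        in_forehead = [
            p for p in pts if fx <= p[0] <= fx + fw and fy <= p[1] <= fy + fh
        ]
        assert len(in_forehead) >= 1

    def test_points_inside_union(self):
        frame = self._checker_frame()
        rois = derive_subrois((20, 10, 100, 100))
        for x, y in extract_points(frame, rois):
            inside = any(
                bx <= x <= bx + bw and by <= y <= by + bh
                for bx, by, bw, bh in (rois.forehead_box, rois.nose_box)
            )
            assert inside

    def test_uniform_frame(self):
        rois = derive_subrois((20, 10, 100, 100))
        with pytest.raises(errors.NoTrackablePoints):
            extract_points(np.full((120, 160), 0.5), rois)

    def test_max_points_truncation(self):
        frame = self._checker_frame()
        rois = derive_subrois((20, 10, 100, 100))
        pts = extract_points(frame, rois, max_points=3)
        counts = []
        for bx, by, bw, bh in (rois.forehead_box, rois.nose_box):
            counts.append(sum(
                1 for x, y in pts if bx <= x <= bx + bw and by <= y <= by + bh
            ))
        assert counts == [3, 3]


class TestTrack:
    fps = 30.0

    def _tracked(self, motion, seed=0):
        frames, roi = make_patch_video(motion, seed=seed)
        seq = FrameSequence(frames=frames, fps=self.fps)
        rois = derive_subrois(roi)
        pts = extract_points(frames[0], rois, max_points=5)
        return seq, pts, track(seq, pts)

    def test_sinusoidal_motion_recovered(self):
        t = np.arange(90) / self.fps
        motion = 2.0 * np.sin(2 * np.pi * 1.2 * t)
        _, _, traj = self._tracked(motion)
        y = traj.fully_valid_matrix()
        assert y.shape[0] >= 1
        for row in y:
            resid = (row - row[0]) - (motion - motion[0])
            assert np.sqrt(np.mean(resid**2)) < 0.3

    def test_static_video(self):
        motion = np.zeros(45)
        _, _, traj = self._tracked(motion)
        for row in traj.fully_valid_matrix():
            assert np.sqrt(np.mean((row - row.mean()) ** 2)) < 0.1

    def test_mean_absolute_error_bound(self):
        t = np.arange(90) / self.fps
        motion = 1.5 * np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        _, _, traj = self._tracked(motion, seed=2)
        errs = [
            np.mean(np.abs((row - row[0]) - (motion - motion[0])))
            for row in traj.fully_valid_matrix()
        ]
        assert np.mean(errs) < 0.5

    def test_patch_exit_invalidates(self):
        # patch slides down 2 px per frame and leaves the frame
        motion = np.arange(60) * 2.0
        frames, roi = make_patch_video(motion, frame_size=(100, 160), patch_size=(40, 80))
        seq = FrameSequence(frames=frames, fps=self.fps)
        rois = derive_subrois(roi)
        pts = extract_points(frames[0], rois, max_points=5)
        with pytest.raises(errors.AllPointsLost):
            track(seq, pts)

    def test_partial_exit_masks_tail(self):
        motion = np.concatenate([np.zeros(10), np.arange(50) * 2.0])
        frames, roi = make_patch_video(motion, frame_size=(100, 160), patch_size=(40, 80))
        # keep one stationary corner outside the patch so not all points die
        frames[:, 5:15, 5:15] = 0.0
        seq = FrameSequence(frames=frames, fps=self.fps)
        rois = derive_subrois(roi)
        pts = np.vstack([extract_points(frames[0], rois, max_points=3), [[10.0, 10.0]]])
        traj = track(seq, pts)
        moving = traj.valid_mask[:-1]
        assert not moving.all(axis=1).any()      # every patch point eventually lost
        assert (~moving[:, 0]).sum() == 0        # but valid at the start
        for row in moving:
            lost = np.flatnonzero(~row)
            assert not row[lost[0]:].any()       # once lost, stays lost

    def test_forward_backward_consistency(self):
        t = np.arange(60) / self.fps
        motion = 2.0 * np.sin(2 * np.pi * 1.2 * t)
        frames, roi = make_patch_video(motion, seed=1)
        seq = FrameSequence(frames=frames, fps=self.fps)
        rois = derive_subrois(roi)
        pts = extract_points(frames[0], rois, max_points=5)
        fwd = track(seq, pts)
        # restart from final tracked positions on the reversed sequence
        final = np.column_stack([
            pts[:, 0], fwd.y[:, -1]  # x assumed constant (pure vertical motion)
        ])
        back = track(FrameSequence(frames=frames[::-1].copy(), fps=self.fps), final)
        assert np.all(np.abs(back.y[:, -1] - fwd.y[:, 0]) < 1.0)


class TestResample:
    def test_identity_at_target_rate(self):
        y = np.random.default_rng(0).normal(size=(3, 90))
        traj = tracking.PointTrajectories(
            y=y, fps=30.0, valid_mask=np.ones_like(y, dtype=bool)
        )
        assert tracking.resample_trajectories(traj, 30.0) is traj

    def test_sixty_to_thirty(self):
        t60 = np.arange(240) / 60.0
        sig = np.sin(2 * np.pi * 1.3 * t60)
        traj = tracking.PointTrajectories(
            y=np.tile(sig, (5, 1)), fps=60.0,
            valid_mask=np.ones((5, 240), dtype=bool),
        )
        out = tracking.resample_trajectories(traj, 30.0)
        assert out.fps == 30.0
        t30 = np.arange(out.n_frames) / 30.0
        assert np.allclose(out.y[0], np.sin(2 * np.pi * 1.3 * t30), atol=1e-3)
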