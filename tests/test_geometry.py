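"""Landmark geometry: alignment, crop boxes, puzzle assembly."""

import numpy as np
import pytest

from dual_atme.geometry import (Box, DegenerateLandmarksError, Landmarks68,
                                align_face, alignment_angle, assemble_puzzle,
                                crop, eyebrow_roi_boxes, face_crop_box,
                                mouth_roi_box, roi_layout)
from dual_atme.synthdata import make_subject

from conftest import landmarks_from


def _box_tuple(b: Box):
    return (b.left, b.top, b.right, b.bottom)


class TestAlignmentAngle:
    @pytest.mark.parametrize("p36, p45, expected", [
        ((100, 120), (200, 120), 0.0),        # level eyes
        ((0, 0), (100, 100), 45.0),           # right eye lower (y down)
        ((0, 0), (100, -100), -45.0),         # right eye higher
    ])
    def test_known_angles(self, p36, p45, expected):
        lm = landmarks_from({36: p36, 45: p45})
        assert alignment_angle(lm) == pytest.approx(expected)

    def test_coincident_eye_corners_raise(self):
        lm = landmarks_from({36: (50, 50), 45: (50, 50)})
        with pytest.raises(DegenerateLandmarksError):
            alignment_angle(lm)


class TestAlignFace:
    def test_zero_angle_is_identity(self, subject):
        img, lm = subject.image, subject.landmarks
        out, lm2 = align_face(img, lm)
        assert np.allclose(out, img)
        assert np.allclose(lm2.points, lm.points)

    def test_known_rotation_recovered(self, subject):
        """Rotating landmarks by +10 deg then aligning recovers eye heights."""
        lm = subject.landmarks
        theta = np.deg2rad(10.0)
        c, s = np.cos(theta), np.sin(theta)
        w, h = lm.image_size
        centre = np.array([(w - 1) / 2, (h - 1) / 2])
        rot = (lm.points - centre) @ np.array([[c, s], [-s, c]]) + centre
        rotated = Landmarks68(rot, lm.image_size)
        assert alignment_angle(rotated) == pytest.approx(10.0, abs=1e-6)
        _, recovered = align_face(subject.image, rotated)
        assert abs(alignment_angle(recovered)) < 0.5
        np.testing.assert_allclose(recovered.points[[36, 45], 1],
                                   lm.points[[36, 45], 1], atol=0.5)

    def test_idempotent(self, subject):
        img1, lm1 = align_face(subject.image, subject.landmarks)
        img2, lm2 = align_face(img1, lm1)
        np.testing.assert_allclose(lm2.points, lm1.points, atol=0.5)
        assert abs(alignment_angle(lm2)) < 0.5


class TestFaceCropBox:
    def _lm(self, shift=(0, 0), scale=1.0):
        dx, dy = shift
        vals = {1: (50, 150), 15: (250, 150), 8: (150, 300), 19: (100, 80),
                20: (110, 78), 38: (112, 98), 23: (190, 79), 43: (188, 109),
                36: (90, 100), 45: (210, 100)}
        return landmarks_from({k: (v[0] * scale + dx, v[1] * scale + dy)
                               for k, v in vals.items()})

    def test_vertical_margin_arithmetic(self):
        # (98-78) and (109-79) average to d = 25
        box = face_crop_box(self._lm())
        assert box.top == pytest.approx(80 - 25)

    def test_boundary_substitution(self):
        assert _box_tuple(face_crop_box(self._lm())) == pytest.approx((50, 55, 250, 300))

    def test_translation_equivariance(self):
        base = face_crop_box(self._lm())
        moved = face_crop_box(self._lm(shift=(7, 11)))
        assert _box_tuple(moved) == pytest.approx(
            (base.left + 7, base.top + 11, base.right + 7, base.bottom + 11))


class TestEyebrowBoxes:
    def _lm(self, scale=1.0):
        vals = {17: (60, 92), 21: (120, 88), 19: (90, 90), 37: (95, 110),
                22: (160, 88), 26: (220, 92), 24: (190, 90), 44: (185, 110)}
        # large canvas so clamping never bites, even at 2x scale
        return landmarks_from({k: (x * scale, y * scale) for k, (x, y) in vals.items()},
                              size=(800, 800))

    def test_left_box_substitution(self):
        # le_l = 60, le_h = 110 - 90 = 20
        left, _ = eyebrow_roi_boxes(self._lm())
        assert _box_tuple(left) == pytest.approx((45, 85, 135, 105))

    def test_scale_equivariance(self):
        left1, right1 = eyebrow_roi_boxes(self._lm())
        left2, right2 = eyebrow_roi_boxes(self._lm(scale=2.0))
        for b1, b2 in ((left1, left2), (right1, right2)):
            assert _box_tuple(b2) == pytest.approx(tuple(2 * v for v in _box_tuple(b1)))

    def test_mirror_symmetric_face(self, subject):
        """On a symmetric face the brow boxes mirror about the midline."""
        lm = subject.landmarks
        sym_pts = (lm.points + lm.mirrored().points) / 2.0
        sym = Landmarks68(sym_pts, lm.image_size)
        left, right = eyebrow_roi_boxes(sym)
        mid = (lm.image_size[0] - 1) / 2.0
        assert right.left == pytest.approx(2 * mid - left.right, abs=1.0)
        assert right.right == pytest.approx(2 * mid - left.left, abs=1.0)
        assert right.top == pytest.approx(left.top, abs=1.0)
        assert right.bottom == pytest.approx(left.bottom, abs=1.0)

    def test_degenerate_raises(self):
        lm = landmarks_from({17: (60, 92), 21: (120, 88), 19: (90, 90), 37: (95, 80),
                             22: (160, 88), 26: (220, 92), 24: (190, 90), 44: (185, 110)})
        with pytest.raises(DegenerateLandmarksError):
            eyebrow_roi_boxes(lm)          # brow below the eyelid: le_h < 0


class TestMouthBox:
    def _lm(self, shift=(0, 0)):
        dx, dy = shift
        vals = {48: (100, 225), 54: (180, 225), 33: (140, 200),
                51: (140, 220), 57: (140, 250)}
        return landmarks_from({k: (x + dx, y + dy) for k, (x, y) in vals.items()})

    def test_boundary_substitution(self):
        # m_l = 80, m_h = 20
        assert _box_tuple(mouth_roi_box(self._lm())) == pytest.approx((80, 210, 200, 260))

    def test_translation_equivariance(self):
        box = mouth_roi_box(self._lm(shift=(-5, 3)))
        assert _box_tuple(box) == pytest.approx((75, 213, 195, 263))

    def test_zero_mouth_height_raises(self):
        lm = self._lm()
        lm.points[51, 1] = lm.points[33, 1]       # lip touches nose base
        with pytest.raises(DegenerateLandmarksError):
            mouth_roi_box(lm)


class TestPuzzle:
    def test_constant_image(self, subject):
        layout = roi_layout(subject.landmarks, puzzle_size=(28, 28))
        img = np.full(subject.image.shape, 7.0)
        out = assemble_puzzle(img, layout)
        assert out.shape == (28, 28)
        np.testing.assert_allclose(out, 7.0)

    def test_quadrants_match_resize_oracle(self, subject):
        """Top-left puzzle quadrant equals the resized left-eyebrow crop."""
        from skimage.transform import resize
        layout = roi_layout(subject.landmarks, puzzle_size=(28, 28))
        h, w = subject.image.shape
        ramp = np.add.outer(np.arange(h, dtype=float), np.arange(w, dtype=float))
        out = assemble_puzzle(ramp, layout)
        expected = resize(crop(ramp, layout.left_eyebrow), (14, 14), order=1,
                          mode="edge", anti_aliasing=False, preserve_range=True)
        np.testing.assert_allclose(out[:14, :14], expected, atol=1e-9)

    def test_mirror_equivariance(self, subject):
        """Puzzle of the mirrored face == mirrored puzzle of the face."""
        lm = subject.landmarks
        sym = Landmarks68((lm.points + lm.mirrored().points) / 2.0, lm.image_size)
        img = subject.image
        sym_img = (img + img[:, ::-1]) / 2.0       # symmetric source image
        out = assemble_puzzle(sym_img, roi_layout(sym, puzzle_size=(28, 28)))
        # crop slices round to integer pixels, so mirroring carries an
        # inherent 1 px offset; compare at resampling tolerance
        diff = np.abs(out - out[:, ::-1])
        assert diff.mean() < 3.0
        assert np.corrcoef(out.ravel(), out[:, ::-1].ravel())[0, 1] > 0.97

    def test_output_size_property(self, subject):
        for size in ((28, 28), (56, 56), (30, 20)):
            layout = roi_layout(subject.landmarks, puzzle_size=size)
            out = assemble_puzzle(subject.image, layout)
            assert out.shape == (size[1], size[0])


def test_boxes_stay_inside_image(tiny_config):
    """Clamped crop geometry is valid on every generated subject."""
    for i in range(tiny_config.n_subjects):
        lm = make_subject(tiny_config, i).landmarks
        w, h = lm.image_size
        layout = roi_layout(lm)
        for box in (layout.face, layout.left_eyebrow, layout.right_eyebrow, layout.mouth):
            assert 0 <= box.left < box.right <= w
            assert 0 <= box.top < box.bottom <= h
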