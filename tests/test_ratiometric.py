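"""Registration recovery, smoothing kernel behaviour, ratio guards and LUT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretpol.io import TwoChannelMovie
from fretpol.ratiometric import (RegistrationModel, apply_registration,
                                 compute_ratio, estimate_registration,
                                 pseudocolor, smooth)
from fretpol.scenes import bead_scene
from fretpol.synthetic import affine_matrix


def _movie(donor, acceptor=None, **kw):
    donor = np.asarray(donor, dtype=float)
    if donor.ndim == 2:
        donor = donor[None]
    acceptor = donor.copy() if acceptor is None else np.asarray(acceptor, float)
    if acceptor.ndim == 2:
        acceptor = acceptor[None]
    defaults = dict(pixel_size=0.27, frame_interval=1.0)
    defaults.update(kw)
    return TwoChannelMovie(donor=donor, acceptor=acceptor, **defaults)


class TestRegistration:
    def test_identity_beads_recover_identity(self):
        model = estimate_registration(bead_scene(8, translation_px=(0, 0)))
        assert np.abs(model.matrix - np.eye(3)).max() < 0.05
        assert model.residual_px < 0.05

    def test_pure_translation_recovered_to_centipixel(self):
        model = estimate_registration(
            bead_scene(10, translation_px=(1.5, -0.5)))
        recovered = np.linalg.inv(model.matrix)[:2, 2]
        assert np.abs(recovered - [1.5, -0.5]).max() < 0.02

    def test_rotation_recovered(self):
        bp = bead_scene(12, translation_px=(2.0, 1.0), rotation_deg=2.0)
        model = estimate_registration(bp)
        injected = affine_matrix((2.0, 1.0), 2.0, center=(64.0, 64.0))
        pts = np.random.default_rng(0).uniform(16, 112, (64, 2))
        a = pts @ np.linalg.inv(model.matrix)[:2, :2].T + np.linalg.inv(model.matrix)[:2, 2]
        b = pts @ injected[:2, :2].T + injected[:2, 2]
        rms = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert rms < 0.1

    def test_two_beads_rejected(self):
        bp = bead_scene(3, translation_px=(1.0, 0.0))
        # keep only 2 beads by blanking one spot
        pos = np.array(bp.meta["bead_positions_px"])
        x, y = pos[0].astype(int)
        bp.donor[0, y - 8:y + 9, x - 8:x + 9] = 0
        bp.acceptor[0, y - 8:y + 9, x - 7:x + 10] = 0
        with pytest.raises(ValueError, match="[Aa]t least 3|matched"):
            estimate_registration(bp)

    def test_collinear_beads_rejected(self):
        X, Y = np.meshgrid(np.arange(128, dtype=float),
                           np.arange(128, dtype=float))
        img = np.zeros((128, 128))
        for x in (20.0, 50.0, 80.0, 110.0):
            img += 1000 * np.exp(-((X - x) ** 2 + (Y - 64.0) ** 2) / (2 * 1.3 ** 2))
        with pytest.raises(ValueError, match="collinear"):
            estimate_registration(_movie(img))


class TestApplyRegistration:
    def test_identity_is_a_no_op(self):
        rng = np.random.default_rng(3)
        movie = _movie(rng.uniform(0, 100, (64, 64)))
        out = apply_registration(movie, RegistrationModel.identity())
        assert np.nanmax(np.abs(out.acceptor - movie.acceptor)) == 0.0

    def test_forward_then_inverse_recovers_interior(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 100, (64, 64))
        movie = _movie(img)
        fwd = RegistrationModel(matrix=affine_matrix((2.0, 0.0)),
                                residual_px=0.0)
        inv = RegistrationModel(matrix=np.linalg.inv(fwd.matrix),
                                residual_px=0.0)
        back = apply_registration(apply_registration(movie, fwd), inv)
        interior = back.acceptor[0, 3:-3, 3:-3]
        assert np.nanmax(np.abs(interior - img[3:-3, 3:-3])) < 1e-6

    def test_applying_twice_differs_from_once(self):
        rng = np.random.default_rng(5)
        movie = _movie(rng.uniform(0, 100, (64, 64)))
        model = RegistrationModel(matrix=affine_matrix((3.0, 1.0)),
                                  residual_px=0.0)
        once = apply_registration(movie, model)
        twice = apply_registration(once, model)
        diff = np.nanmax(np.abs(once.acceptor - twice.acceptor))
        assert diff > 1.0

    def test_donor_untouched(self):
        rng = np.random.default_rng(6)
        movie = _movie(rng.uniform(0, 100, (32, 32)))
        model = RegistrationModel(matrix=affine_matrix((1.3, -0.7)),
                                  residual_px=0.0)
        out = apply_registration(movie, model)
        assert np.array_equal(out.donor, movie.donor)


class TestSmooth:
    def test_constant_image_unchanged(self):
        movie = _movie(np.full((32, 32), 7.0))
        out = smooth(movie, 2)
        assert np.allclose(out.donor, 7.0)

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(7)
        movie = _movie(rng.uniform(0, 10, (16, 16)))
        out = smooth(movie, 0)
        assert np.array_equal(out.donor, movie.donor)

    def test_single_pixel_spreads_over_13_pixel_disk(self):
        img = np.zeros((15, 15))
        img[7, 7] = 13.0
        out = smooth(_movie(img), 2).donor[0]
        # discrete radius-2 disk: 13 pixels, each receiving value/13
        assert np.isclose(out[7, 7], 1.0)
        assert np.isclose(out[7, 5], 1.0)      # |dx| = 2 on-axis included
        assert np.isclose(out[5, 5], 0.0)      # corner excluded
        assert np.isclose(np.count_nonzero(out), 13)

    def test_interior_sum_conserved(self):
        rng = np.random.default_rng(8)
        img = np.zeros((40, 40))
        img[5:-5, 5:-5] = rng.uniform(0, 10, (30, 30))
        out = smooth(_movie(img), 2).donor[0]
        assert np.abs(out.sum() / img.sum() - 1) < 1e-6

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            smooth(_movie(np.ones((8, 8))), -1)


class TestComputeRatio:
    def test_constant_double_acceptor(self):
        donor = np.full((16, 16), 50.0)
        rm = compute_ratio(_movie(donor, 2 * donor), donor_floor=1.0)
        assert np.allclose(rm.ratio[rm.valid], 2.0)
        assert rm.valid.all()

    def test_zero_donor_pixel_invalid_not_infinite(self):
        donor = np.full((8, 8), 50.0)
        donor[3, 3] = 0.0
        rm = compute_ratio(_movie(donor, np.full((8, 8), 25.0)),
                           donor_floor=1.0)
        assert not rm.valid[0, 3, 3]
        assert np.isfinite(rm.ratio[rm.valid]).all()

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            compute_ratio(_movie(np.ones((8, 8))), donor_floor=-1.0)

    @settings(deadline=None, max_examples=25)
    @given(gain=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=99))
    def test_scale_invariance(self, gain, seed):
        """Multiplying both channels by any gain leaves every defined ratio
        pixel unchanged (to 1e-12)."""
        rng = np.random.default_rng(seed)
        donor = rng.uniform(10, 100, (12, 12))
        acceptor = donor * rng.uniform(0.5, 2.0, (12, 12))
        a = compute_ratio(_movie(donor, acceptor), donor_floor=0.0)
        b = compute_ratio(_movie(donor * gain, acceptor * gain),
                          donor_floor=0.0)
        assert np.array_equal(a.valid, b.valid)
        assert np.nanmax(np.abs(a.ratio - b.ratio)) < 1e-12


class TestPseudocolor:
    def _ratio_movie(self, values):
        donor = np.full((1, 1, len(values)), 10.0)
        acceptor = donor * np.asarray(values)[None, None, :]
        return compute_ratio(_movie(donor, acceptor), donor_floor=1.0)

    def test_clamping_at_range_ends(self):
        rm = self._ratio_movie([0.1, 5.0])
        img = pseudocolor(rm, (1.0, 2.0))
        low = pseudocolor(self._ratio_movie([1.0]), (1.0, 2.0))
        assert np.array_equal(img[0, 0, 0], low[0, 0, 0])   # below -> bottom
        top = pseudocolor(self._ratio_movie([1.999]), (1.0, 2.0))
        assert np.array_equal(img[0, 0, 1], top[0, 0, 0])   # above -> top

    def test_sixteen_even_levels_all_distinct(self):
        vals = 1.0 + (np.arange(16) + 0.5) / 16.0
        img = pseudocolor(self._ratio_movie(vals), (1.0, 2.0))
        colors = {tuple(c) for c in img[0, 0]}
        assert len(colors) == 16

    def test_invalid_pixels_get_background(self):
        donor = np.zeros((1, 2, 2))
        acceptor = np.ones((1, 2, 2))
        rm = compute_ratio(TwoChannelMovie(donor=donor, acceptor=acceptor,
                                           pixel_size=0.27,
                                           frame_interval=1.0),
                           donor_floor=1.0)
        img = pseudocolor(rm, (1.0, 2.0))
        assert np.array_equal(img[0, 0, 0], [0, 0, 0])

    def test_bad_range_rejected(self):
        rm = self._ratio_movie([1.0])
        with pytest.raises(ValueError):
            pseudocolor(rm, (2.0, 1.0))
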