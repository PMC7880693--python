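"""Feret axis, axial profiling, binning/normalization and loess."""

import numpy as np
import pytest

from glandscan.io import PolygonROI
from glandscan.profiling import (
    AxialProfile,
    bin_and_aggregate,
    feret_axis,
    loess_smooth,
    normalize_profile,
    profile_along_axis,
)
from glandscan.synthetic import (
    ChannelProfile,
    GlandSpec,
    ProfileSpec,
    make_gland_roi,
    render_gland_image,
)

from conftest import random_simple_polygon


def brute_force_feret(vertices: np.ndarray) -> float:
    best = 0.0
    for i in range(len(vertices)):
        for j in range(i + 1, len(vertices)):
            best = max(best, float(np.linalg.norm(vertices[i] - vertices[j])))
    return best


class TestFeretAxis:
    def test_unit_square_diagonal(self):
        ax = feret_axis(PolygonROI([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert ax.length_px == pytest.approx(np.sqrt(2))
        assert abs(ax.angle_deg) == pytest.approx(45.0)

    def test_rectangle_by_hand(self):
        ax = feret_axis(PolygonROI([[0, 0], [10, 0], [10, 2], [0, 2]]))
        assert ax.length_px == pytest.approx(np.sqrt(104))
        assert abs(ax.angle_deg) == pytest.approx(np.degrees(np.arctan(2 / 10)))

    def test_equals_pairwise_oracle_on_random_polygons(self, rng):
        for _ in range(100):
            roi = random_simple_polygon(rng)
            assert feret_axis(roi).length_px == pytest.approx(
                brute_force_feret(roi.vertices), abs=1e-12
            )

    def test_angle_in_halfopen_interval(self, rng):
        for _ in range(50):
            a = feret_axis(random_simple_polygon(rng)).angle_deg
            assert -90 < a <= 90

    def test_degenerate_polygon_rejected(self):
        roi = PolygonROI.__new__(PolygonROI)
        roi.vertices = np.zeros((4, 2))
        roi.label = roi.anchor = None
        with pytest.raises(ValueError, match="degenerate"):
            feret_axis(roi)


class TestProfileAlongAxis:
    @pytest.mark.parametrize("rotation", [0, 30])
    def test_uniform_intensity_flat_profile(self, rotation):
        geom = make_gland_roi(
            GlandSpec(length_px=100, width_px=24, rotation_deg=rotation,
                      image_shape=(160, 160))
        )
        spec = ProfileSpec(channels={"c": ChannelProfile("constant", (50.0,))})
        img, _ = render_gland_image(geom, spec, seed=0)
        prof = profile_along_axis(img, geom.gland, "c")
        tol = 0.0 if rotation == 0 else 0.005 * 50.0
        assert np.abs(prof.mean_intensity - 50.0).max() <= tol + 1e-9

    def test_linear_gradient_recovered(self, straight_gland, linear_profile_spec):
        img, truth = render_gland_image(straight_gland, linear_profile_spec, seed=0)
        prof = profile_along_axis(img, straight_gland.gland, "sig")
        rel = prof.positions / prof.axis_length_px
        expected = 200.0 * rel
        # interior positions reproduce the analytic gradient closely
        interior = (rel > 0.1) & (rel < 0.9)
        assert np.abs(prof.mean_intensity[interior] - expected[interior]).max() < 4.0

    def test_orientation_follows_anchor(self, straight_gland, linear_profile_spec):
        img, _ = render_gland_image(straight_gland, linear_profile_spec, seed=0)
        prof = profile_along_axis(img, straight_gland.gland, "sig")
        assert prof.oriented
        # gradient rises away from the proximal anchor
        assert prof.mean_intensity[-1] > prof.mean_intensity[0]
        unoriented = profile_along_axis(
            img, PolygonROI(straight_gland.gland.vertices), "sig"
        )
        assert not unoriented.oriented

    def test_rotation_invariance_of_binned_profile(self, linear_profile_spec):
        binned = {}
        for rot in (0, 17, 30, 63):
            geom = make_gland_roi(
                GlandSpec(length_px=120, width_px=30, rotation_deg=rot,
                          image_shape=(200, 200))
            )
            img, _ = render_gland_image(geom, linear_profile_spec, seed=1)
            prof = profile_along_axis(img, geom.gland, "sig", gland_id=f"r{rot}")
            binned[rot] = bin_and_aggregate(
                [prof], n_bins=128, normalization="none", smooth=False
            ).mean
        ref = binned[0]
        for rot in (17, 30, 63):
            both = ~np.isnan(ref) & ~np.isnan(binned[rot])
            dev = np.abs(binned[rot][both] - ref[both]).max()
            assert dev < 0.02 * 200.0


class TestNormalizeProfile:
    def _profile(self, values, gland="g", channel="c"):
        values = np.asarray(values, dtype=float)
        return AxialProfile(
            gland_id=gland, channel=channel,
            positions=np.arange(len(values)), mean_intensity=values,
            n_pixels=np.ones(len(values), dtype=int), axis_length_px=float(len(values)),
            oriented=True,
        )

    def test_identity_when_signal_equals_reference(self):
        p = self._profile([2.0, 4.0, 8.0])
        out = normalize_profile(p, self._profile([2.0, 4.0, 8.0]))
        np.testing.assert_allclose(out.mean_intensity, 1.0, rtol=1e-5)

    def test_constant_reference_scales(self):
        out = normalize_profile(
            self._profile([10.0, 20.0, 30.0]), self._profile([5.0, 5.0, 5.0])
        )
        np.testing.assert_allclose(out.mean_intensity, [2.0, 4.0, 6.0], rtol=1e-5)

    def test_zero_reference_stays_finite_and_flagged(self):
        out = normalize_profile(
            self._profile([1.0, 1.0, 1.0]), self._profile([0.0, 2.0, 2.0])
        )
        assert np.isfinite(out.mean_intensity).all()
        assert out.dropped_positions == [0]

    def test_mismatched_grids_rejected(self):
        a = self._profile([1.0, 2.0, 3.0])
        b = self._profile([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="position grids"):
            normalize_profile(a, b)


class TestBinAndAggregate:
    def _profile(self, values, gland="g"):
        values = np.asarray(values, dtype=float)
        return AxialProfile(
            gland_id=gland, channel="c",
            positions=np.arange(len(values)), mean_intensity=values,
            n_pixels=np.full(len(values), 3, dtype=int),
            axis_length_px=float(len(values)), oriented=True,
        )

    def test_two_identical_glands_average_to_each(self):
        vals = np.linspace(1, 5, 50)
        out = bin_and_aggregate(
            [self._profile(vals, "a"), self._profile(vals, "b")],
            n_bins=25, normalization="none", smooth=False,
        )
        single = bin_and_aggregate(
            [self._profile(vals, "a")], n_bins=25, normalization="none", smooth=False
        )
        np.testing.assert_allclose(out.mean, single.mean)
        assert (out.sd[out.n_glands > 1] == 0).all()

    def test_per_gland_mean_normalization_identity(self, rng):
        vals = rng.uniform(1, 10, 200)
        out = bin_and_aggregate(
            [self._profile(vals)], n_bins=50, normalization="per-gland-mean",
            smooth=False,
        )
        # mean over bins weighted by per-bin position counts recovers 1
        idx = np.clip(((np.arange(200) / 200.0) * 50).astype(int), 0, 49)
        counts = np.bincount(idx, minlength=50)
        weighted = np.nansum(out.mean * counts) / counts.sum()
        assert weighted == pytest.approx(1.0, abs=1e-12)

    def test_proportional_profiles_normalize_identically(self):
        base = np.linspace(1, 3, 80)
        out_b = bin_and_aggregate([self._profile(base)], n_bins=40, smooth=False)
        out_2b = bin_and_aggregate([self._profile(2 * base)], n_bins=40, smooth=False)
        np.testing.assert_allclose(out_b.mean, out_2b.mean, rtol=1e-12)

    def test_mixed_orientation_rejected(self):
        a = self._profile(np.arange(10.0), "a")
        b = self._profile(np.arange(10.0), "b")
        b.oriented = False
        with pytest.raises(ValueError, match="oriented"):
            bin_and_aggregate([a, b])


class TestLoess:
    def test_reproduces_linear_data_exactly(self):
        x = np.linspace(0, 1, 256)
        y = 3.0 * x - 1.0
        for span, degree in [(0.05, 2), (0.3, 1), (1.0, 1), (1.0, 2)]:
            out = loess_smooth(x, y, span=span, degree=degree)
            np.testing.assert_allclose(out, y, atol=1e-9)

    def test_constant_input_constant_output(self):
        x = np.linspace(0, 1, 100)
        out = loess_smooth(x, np.full(100, 7.0), span=0.1)
        np.testing.assert_allclose(out, 7.0, atol=1e-9)

    def test_noisy_sine_rmse(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 2 * np.pi, 300)
        truth = np.sin(x)
        y = truth + rng.normal(0, 0.2, 300)
        out = loess_smooth(x, y, span=0.3, degree=2)
        rmse = np.sqrt(np.mean((out - truth) ** 2))
        assert rmse < 0.2

    def test_rank_deficient_window_raises_with_location(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="loess window"):
            loess_smooth(x, x**2, span=0.05, degree=2)  # k=1 < degree+1

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(10.0), np.arange(10.0), span=0.0)
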