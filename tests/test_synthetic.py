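"""Ground-truth consistency and determinism of the synthetic generator."""

import numpy as np
import pytest

from glandscan.io import PolygonROI, rasterize
from glandscan.synthetic import (
    ChannelProfile,
    GlandSpec,
    NucleiSpec,
    ProfileSpec,
    make_gland_roi,
    render_gland_image,
    render_hemocyte_channel,
    render_nuclei_stack,
)


def rect_roi(x0, x1, y0, y1):
    return PolygonROI([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


class TestMakeGlandRoi:
    def test_axis_aligned_capsule_feret_equals_length(self, straight_gland):
        v = straight_gland.gland.vertices
        d = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(-1)).max()
        assert d == pytest.approx(100.0, abs=0.5)

    @pytest.mark.parametrize("rotation,bend", [(0, 0), (30, 0), (17, 8), (63, 0)])
    def test_compartments_tile_gland_mask(self, rotation, bend):
        spec = GlandSpec(
            length_px=100, width_px=20, rotation_deg=rotation,
            bend_amplitude_px=bend, image_shape=(160, 160),
        )
        geom = make_gland_roi(spec)
        gland = rasterize(geom.gland, spec.image_shape)
        pp = rasterize(geom.proximal, spec.image_shape)
        dp = rasterize(geom.distal, spec.image_shape)
        assert ((pp | dp) == gland).all()
        assert not (pp & dp).any()

    def test_same_spec_gives_identical_vertices(self):
        spec = GlandSpec(length_px=80, width_px=18, rotation_deg=23.0)
        a = make_gland_roi(spec)
        b = make_gland_roi(spec)
        np.testing.assert_array_equal(a.gland.vertices, b.gland.vertices)
        assert a.anchor == b.anchor

    def test_anchor_is_proximal_tip(self, straight_gland):
        # axial position at the anchor is 0; at the opposite tip it is 1
        s = straight_gland.axial_position(np.array([straight_gland.anchor]))
        assert s[0] == pytest.approx(0.0, abs=0.01)

    def test_oversized_gland_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            make_gland_roi(GlandSpec(length_px=300, width_px=20, image_shape=(100, 100)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GlandSpec(length_px=50, width_px=60)


class TestRenderGlandImage:
    def test_constant_profile_noise_free_is_exact(self, straight_gland):
        spec = ProfileSpec(channels={"c": ChannelProfile("constant", (100.0,))})
        img, truth = render_gland_image(straight_gland, spec, seed=0)
        chan = img.channel("c")
        assert (chan[truth.mask] == 100.0).all()
        assert (chan[~truth.mask] == 0.0).all()

    def test_linear_profile_matches_analytic_gradient(self, straight_gland, linear_profile_spec):
        img, truth = render_gland_image(straight_gland, linear_profile_spec, seed=0)
        chan = img.channel("sig")
        expected = 200.0 * truth.axial_map[truth.mask]
        np.testing.assert_allclose(chan[truth.mask], expected, atol=1e-4)

    def test_gaussian_noise_mean_within_clt_bound(self, straight_gland):
        spec = ProfileSpec(
            channels={"c": ChannelProfile("constant", (100.0,))}, gaussian_sigma=5.0
        )
        img, truth = render_gland_image(straight_gland, spec, seed=1)
        inside = img.channel("c")[truth.mask]
        n = inside.size
        assert n >= 1500
        assert abs(inside.mean() - 100.0) < 3 * 5.0 / np.sqrt(n)

    def test_step_profile_two_plateaus(self, straight_gland):
        spec = ProfileSpec(channels={"c": ChannelProfile("step", (40.0, 160.0, 0.5))})
        img, truth = render_gland_image(straight_gland, spec, seed=0)
        chan = img.channel("c")
        vals = set(np.unique(chan[truth.mask]))
        assert vals == {40.0, 160.0}

    def test_determinism(self, straight_gland, linear_profile_spec):
        a, _ = render_gland_image(straight_gland, linear_profile_spec, seed=5)
        b, _ = render_gland_image(straight_gland, linear_profile_spec, seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestHemocyteChannel:
    def test_zero_fraction_zero_pixels(self, straight_gland):
        img, count = render_hemocyte_channel(straight_gland, 0.0, seed=0)
        assert count == 0 and not img.any()

    def test_returned_count_equals_rendered_foreground(self, straight_gland):
        img, count = render_hemocyte_channel(straight_gland, 0.08, seed=3)
        assert count == int((img > 0).sum())

    def test_count_within_one_patch_of_target(self, straight_gland):
        frac, radius = 0.10, 4.0
        img, count = render_hemocyte_channel(
            straight_gland, frac, patch_radius_px=radius, seed=2
        )
        area = rasterize(straight_gland.gland, straight_gland.spec.image_shape).sum()
        patch_area = ((np.mgrid[-4:5, -4:5] ** 2).sum(0) <= radius**2).sum()
        assert abs(count - frac * area) <= patch_area

    def test_restricted_patches_stay_in_compartment(self, straight_gland):
        img, count = render_hemocyte_channel(
            straight_gland, 0.05, restrict_to="DP", seed=1
        )
        dp = rasterize(straight_gland.distal, straight_gland.spec.image_shape)
        assert count > 0
        assert (img[~dp] == 0).all()

    def test_impossible_fraction_raises(self, straight_gland):
        with pytest.raises(RuntimeError):
            render_hemocyte_channel(
                straight_gland, 0.95, patch_radius_px=6.0, seed=0, max_failures=200
            )


class TestNucleiStack:
    pp = rect_roi(4.5, 60.5, 4.5, 75.5)
    dp = rect_roi(64.5, 120.5, 4.5, 75.5)

    def spec(self, **kw):
        defaults = dict(
            n_proximal=4, n_distal=4, radius_um_proximal=2.0, radius_um_distal=2.5,
            radius_spread_um=0.0, stack_shape=(20, 80, 126),
        )
        defaults.update(kw)
        return NucleiSpec(**defaults)

    def test_voxel_count_matches_enumeration_oracle(self):
        stack, truth, labels = render_nuclei_stack(
            self.spec(n_proximal=1, n_distal=0, radius_um_proximal=2.5),
            self.pp, self.dp, seed=4,
        )
        row = truth.iloc[0]
        # independent brute-force enumeration over the whole volume
        zz, yy, xx = np.mgrid[0:20, 0:80, 0:126]
        dz, dy, dx = 1.0, 0.5, 0.5
        r = row.radius_um
        inside = (
            ((zz - row.z) * dz / r) ** 2
            + ((yy - row.y) * dy / r) ** 2
            + ((xx - row.x) * dx / r) ** 2
        ) <= 1.0
        assert int(inside.sum()) == row.voxel_count == (labels == 1).sum()

    def test_perfect_log_correlation_degenerate(self):
        spec = self.spec(channel_log_correlation=1.0, channel_log_sds=(0.3, 0.3))
        _, truth, _ = render_nuclei_stack(spec, self.pp, self.dp, seed=0)
        a = truth.log10_total_a - spec.channel_log_means[0]
        b = truth.log10_total_b - spec.channel_log_means[1]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_rendered_totals_exact_on_labels(self):
        stack, truth, labels = render_nuclei_stack(self.spec(), self.pp, self.dp, seed=1)
        ch = stack.channel("dl").astype(np.float64)
        for _, row in truth.iterrows():
            assert ch[labels == row.label].sum() == pytest.approx(
                row.total_a_rendered, rel=1e-6
            )

    def test_centroids_in_declared_compartment(self):
        _, truth, _ = render_nuclei_stack(self.spec(), self.pp, self.dp, seed=2)
        for _, row in truth.iterrows():
            roi = self.pp if row.compartment == "PP" else self.dp
            assert roi.contains_points(np.array([[row.x, row.y]]))[0]

    def test_determinism(self):
        a = render_nuclei_stack(self.spec(), self.pp, self.dp, seed=9)
        b = render_nuclei_stack(self.spec(), self.pp, self.dp, seed=9)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[2], b[2])

    def test_radius_below_two_voxels_rejected(self):
        with pytest.raises(ValueError, match="2 voxels"):
            NucleiSpec(radius_um_proximal=1.5, voxel_size_um=(1.0, 0.5, 0.5))
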