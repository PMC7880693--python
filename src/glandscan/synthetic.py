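"""Synthetic gland images with exact ground truth.

Real larval salivary glands are elongated, gently curved epithelial tubes;
the raw confocal images behind the published measurements are not publicly
available, so every downstream stage of this package is exercised on
generated images whose geometry, axial intensity profile, hemocyte patch
area and per-nucleus properties are known exactly.

Conventions (shared with :mod:`glandscan.io`):

* a pixel/voxel belongs to a shape iff its **center** lies inside it
  (even-odd rule for polygons, ``Σ((v−c)/r)² ≤ 1`` for ellipsoids);
* noise is applied to intensities only, never to geometry, so geometric
  ground truth (masks, pixel counts, axial-position maps) is exact;
* every generator is a pure function of its spec and a single integer seed;
  independent sub-streams for geometry, placement and noise are derived
  deterministically from that seed.

The gland outline is a rounded capsule: the offset curve (half-width
``width_px/2``) of a centerline running tip-to-tip, optionally bent into a
half sine wave and rotated.  A pixel's relative axial position ``s ∈ [0, 1]``
is the normalized arc-length coordinate of its nearest centerline point;
the proximal/distal split sits at ``s = 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import CalibratedImage, PolygonROI, points_in_polygon, rasterize

__all__ = [
    "GlandSpec",
    "ChannelProfile",
    "ProfileSpec",
    "NucleiSpec",
    "GlandGeometry",
    "ImageGroundTruth",
    "make_gland_roi",
    "render_gland_image",
    "render_hemocyte_channel",
    "render_nuclei_stack",
]

_N_CENTERLINE = 1024  # samples used for arc-length parameterization
_N_TRUTH_SAMPLES = 1000  # ground-truth profile sample points


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GlandSpec:
    """Geometry of one synthetic gland within an image frame."""

    length_px: int = 150
    width_px: int = 36
    rotation_deg: float = 0.0
    bend_amplitude_px: float = 0.0
    image_shape: tuple[int, int] = (140, 200)  # (rows, cols)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.length_px <= 0 or self.width_px <= 0:
            raise ValueError("length_px and width_px must be positive")
        if self.width_px >= self.length_px:
            raise ValueError("width_px must be smaller than length_px")
        if self.bend_amplitude_px < 0:
            raise ValueError("bend_amplitude_px must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class ChannelProfile:
    """Axial intensity function I(s) for one channel, s ∈ [0, 1].

    Supported forms: ``constant`` (value,), ``linear`` (a, b) → a + b·s,
    and ``step`` (proximal, distal, s0) — a proximal/distal plateau pair
    with the boundary at s0.
    """

    kind: Literal["constant", "linear", "step"]
    params: tuple[float, ...]

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.kind == "constant":
            return np.full_like(s, self.params[0])
        if self.kind == "linear":
            a, b = self.params
            return a + b * s
        if self.kind == "step":
            lo, hi, s0 = self.params
            return np.where(s < s0, lo, hi)
        raise ValueError(f"unknown profile kind {self.kind!r}")

    def __post_init__(self) -> None:
        probe = self(np.linspace(0.0, 1.0, 101))
        if np.any(probe < 0):
            raise ValueError("intensity function must be non-negative on [0, 1]")


@dataclass(frozen=True)
class ProfileSpec:
    """Per-channel axial intensities plus the noise model for one image."""

    channels: dict[str, ChannelProfile]
    background_level: float = 0.0
    gaussian_sigma: float = 0.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be non-negative")


@dataclass(frozen=True)
class NucleiSpec:
    """Two-compartment nuclear population for a 3-channel z-stack.

    The DAPI channel carries uniform-intensity digital ellipsoids; the two
    marker channels carry per-nucleus totals drawn from a bivariate normal
    on log10 scale with correlation ``channel_log_correlation``, spread
    uniformly over each nucleus' voxels.
    """

    n_proximal: int = 15
    n_distal: int = 15
    radius_um_proximal: float = 2.0
    radius_um_distal: float = 2.0
    radius_spread_um: float = 0.2
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (dz, dy, dx)
    stack_shape: tuple[int, int, int] = (24, 140, 200)  # (Z, Y, X)
    channel_log_correlation: float = 0.8
    channel_log_means: tuple[float, float] = (3.0, 3.0)
    channel_log_sds: tuple[float, float] = (0.3, 0.3)
    dapi_intensity: float = 200.0
    dapi_background: float = 10.0
    gaussian_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.channel_log_correlation <= 1.0:
            raise ValueError("channel_log_correlation must lie in [-1, 1]")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        for r in (self.radius_um_proximal, self.radius_um_distal):
            rmin = r - self.radius_spread_um
            if any(rmin / v < 2.0 for v in self.voxel_size_um):
                raise ValueError(
                    "nuclear radius must span at least 2 voxels in every axis"
                )


# ---------------------------------------------------------------------------
# geometry


@dataclass
class GlandGeometry:
    """A generated gland: ROIs, centerline, and the exact axial-position map."""

    gland: PolygonROI
    proximal: PolygonROI
    distal: PolygonROI
    anchor: tuple[float, float]  # proximal tip, (x, y)
    centerline: np.ndarray  # (N, 2) points, proximal → distal
    arc_s: np.ndarray  # (N,) normalized arc length of each centerline point
    spec: GlandSpec

    def axial_position(self, points: np.ndarray) -> np.ndarray:
        """Relative axial position s ∈ [0, 1] of each (x, y) point:
        the normalized arc-length coordinate of its nearest centerline point."""
        tree = cKDTree(self.centerline)
        _, idx = tree.query(np.atleast_2d(points))
        return self.arc_s[idx]

    def axial_position_map(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Dense s-map over the pixel grid (values valid inside the gland)."""
        rows, cols = image_shape
        cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
        pts = np.column_stack([cc.ravel(), rr.ravel()])
        return self.axial_position(pts).reshape(rows, cols)


def _centerline(spec: GlandSpec) -> tuple[np.ndarray, np.ndarray]:
    """Centerline samples (rotated, translated into the image frame) and
    their normalized arc-length coordinates."""
    t = np.linspace(0.0, 1.0, _N_CENTERLINE)
    pts = np.column_stack(
        [t * spec.length_px, spec.bend_amplitude_px * np.sin(np.pi * t)]
    )
    pts = _place_in_frame(pts, spec)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, arc / arc[-1]


def _place_in_frame(pts: np.ndarray, spec: GlandSpec) -> np.ndarray:
    """Rotate local-frame points about their midpoint and center in the image."""
    theta = np.deg2rad(spec.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mid = np.array([spec.length_px / 2.0, 0.0])
    rows, cols = spec.image_shape
    center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    return (pts - mid) @ rot.T + center


def make_gland_roi(spec: GlandSpec) -> GlandGeometry:
    """Construct the capsule outline plus proximal/distal sub-ROIs.

    The sub-ROIs share their boundary vertices with the gland outline and
    with each other (the cut at s = 0.5), so their rasterized masks tile the
    gland mask exactly under the half-open even-odd rule.

    Raises ``ValueError`` if the gland does not fit in ``image_shape`` with
    a 2-pixel margin.
    """
    w2 = spec.width_px / 2.0
    t = np.linspace(0.0, 1.0, _N_CENTERLINE)
    local = np.column_stack(
        [t * spec.length_px, spec.bend_amplitude_px * np.sin(np.pi * t)]
    )
    seg = np.linalg.norm(np.diff(local, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= spec.width_px:
        raise ValueError("centerline shorter than gland width")

    # offset-curve support: arc positions from w/2 to total-w/2, odd count so
    # the exact midpoint (the PP/DP cut) is a shared vertex
    m = 129
    arc_grid = np.linspace(w2, total - w2, m)
    i_mid = m // 2

    def at_arc(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.interp(a, arc, local[:, 0])
        y = np.interp(a, arc, local[:, 1])
        # tangent by central differences on the interpolated curve
        eps = total / (_N_CENTERLINE * 4)
        xm = np.interp(np.clip(a - eps, 0, total), arc, local[:, 0])
        ym = np.interp(np.clip(a - eps, 0, total), arc, local[:, 1])
        xp = np.interp(np.clip(a + eps, 0, total), arc, local[:, 0])
        yp = np.interp(np.clip(a + eps, 0, total), arc, local[:, 1])
        tan = np.column_stack([xp - xm, yp - ym])
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        return np.column_stack([x, y]), tan

    c, tan = at_arc(arc_grid)
    normal = np.column_stack([-tan[:, 1], tan[:, 0]])
    left = c + w2 * normal  # +N side
    right = c - w2 * normal  # −N side

    def cap(center: np.ndarray, tangent: np.ndarray, outward: float) -> np.ndarray:
        """Semicircle from +N to −N through the tip (±T direction), endpoints
        excluded (they are the adjacent offset-curve vertices)."""
        nvec = np.array([-tangent[1], tangent[0]])
        tvec = tangent * outward
        ang = np.linspace(0.0, np.pi, 35)[1:-1]
        return center[None, :] + w2 * (
            np.cos(ang)[:, None] * nvec[None, :] + np.sin(ang)[:, None] * tvec[None, :]
        )

    prox_cap = cap(c[0], tan[0], outward=-1.0)[::-1]  # right[0] → ... → left[0]
    dist_cap = cap(c[-1], tan[-1], outward=+1.0)  # left[-1] → ... → right[-1]

    gland_v = np.vstack([prox_cap, left, dist_cap, right[::-1]])
    pp_v = np.vstack(
        [prox_cap, left[: i_mid + 1], right[: i_mid + 1][::-1]]
    )
    dp_v = np.vstack(
        [left[i_mid:], dist_cap, right[i_mid:][::-1]]
    )

    tip = c[0] - w2 * tan[0]
    all_pts = [_place_in_frame(v, spec) for v in (gland_v, pp_v, dp_v)]
    anchor = tuple(_place_in_frame(tip[None, :], spec)[0])

    rows, cols = spec.image_shape
    allv = np.vstack(all_pts)
    if (
        allv[:, 0].min() < 2
        or allv[:, 1].min() < 2
        or allv[:, 0].max() > cols - 3
        or allv[:, 1].max() > rows - 3
    ):
        raise ValueError(
            f"gland (length {spec.length_px}, width {spec.width_px}, rotation "
            f"{spec.rotation_deg}°) does not fit in image {spec.image_shape} "
            "with a 2-px margin"
        )

    centerline, arc_s = _centerline(spec)
    return GlandGeometry(
        gland=PolygonROI(all_pts[0], label="gland", anchor=anchor),
        proximal=PolygonROI(all_pts[1], label="PP", anchor=anchor),
        distal=PolygonROI(all_pts[2], label="DP"),
        anchor=anchor,
        centerline=centerline,
        arc_s=arc_s,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# 2D rendering


@dataclass
class ImageGroundTruth:
    """Exact truth for a rendered 2D gland image."""

    seed: int
    mask: np.ndarray  # gland mask (bool)
    axial_map: np.ndarray  # s per pixel (valid inside mask)
    profile_s: np.ndarray  # 1000 sample positions on [0, 1]
    profile_values: dict[str, np.ndarray]  # true I(s) per channel
    foreground_count: int = 0  # hemocyte patches, if rendered


def render_gland_image(
    geometry: GlandGeometry,
    profile_spec: ProfileSpec,
    seed: int = 0,
) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Paint each channel's axial intensity onto the gland, plus noise.

    Inside-gland pixels carry ``I_c(s)`` evaluated at the pixel's true axial
    position; outside pixels carry the background level.  Gaussian noise
    (sd ``gaussian_sigma``) and/or Poisson resampling are applied to the
    intensities only; the returned ground truth stores the exact mask, the
    axial-position map and the true profile at 1000 sample points.
    """
    spec = geometry.spec
    mask = rasterize(geometry.gland, spec.image_shape)
    smap = geometry.axial_position_map(spec.image_shape)
    rng_noise = _substream(seed, "noise")

    names = list(profile_spec.channels)
    data = np.empty((len(names), *spec.image_shape), dtype=np.float64)
    for i, name in enumerate(names):
        fn = profile_spec.channels[name]
        chan = np.full(spec.image_shape, profile_spec.background_level, dtype=float)
        chan[mask] = fn(smap[mask])
        if profile_spec.poisson:
            chan = rng_noise.poisson(np.clip(chan, 0, None)).astype(float)
        if profile_spec.gaussian_sigma > 0:
            chan = chan + rng_noise.normal(0, profile_spec.gaussian_sigma, chan.shape)
        data[i] = chan

    s_grid = np.linspace(0.0, 1.0, _N_TRUTH_SAMPLES)
    truth = ImageGroundTruth(
        seed=seed,
        mask=mask,
        axial_map=smap,
        profile_s=s_grid,
        profile_values={n: profile_spec.channels[n](s_grid) for n in names},
    )
    image = CalibratedImage(
        data=data.astype(np.float32),
        pixel_size_um=(spec.pixel_size_um, spec.pixel_size_um),
        channels=names,
    )
    return image, truth


def render_hemocyte_channel(
    geometry: GlandGeometry,
    target_fraction: float,
    patch_radius_px: float = 4.0,
    restrict_to: Literal["PP", "DP", "whole"] = "whole",
    seed: int = 0,
    intensity: float = 200.0,
    max_failures: int = 20000,
) -> tuple[np.ndarray, int]:
    """Stamp disjoint bright disks onto the chosen gland compartment.

    Disks are placed greedily at uniformly sampled in-compartment pixel
    centers until the foreground covers ``target_fraction`` of the
    compartment area; the returned true pixel count equals the rendered
    foreground count exactly.  Raises ``RuntimeError`` if disjoint placement
    stalls more than one patch area short of the target.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    spec = geometry.spec
    roi = {"PP": geometry.proximal, "DP": geometry.distal, "whole": geometry.gland}[
        restrict_to
    ]
    allowed = rasterize(roi, spec.image_shape)
    area = int(allowed.sum())
    image = np.zeros(spec.image_shape, dtype=np.float32)
    target = int(round(target_fraction * area))
    if target == 0:
        return image, 0

    r = int(np.ceil(patch_radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (dy**2 + dx**2) <= patch_radius_px**2
    offs = np.argwhere(disk) - r  # (k, 2) row/col offsets
    patch_area = len(offs)

    rng = _substream(seed, "placement")
    candidates = np.argwhere(allowed)
    foreground = np.zeros_like(allowed)
    count = 0
    failures = 0
    while count < target:
        center = candidates[rng.integers(len(candidates))]
        cells = offs + center
        ok = (
            (cells[:, 0] >= 0)
            & (cells[:, 0] < spec.image_shape[0])
            & (cells[:, 1] >= 0)
            & (cells[:, 1] < spec.image_shape[1])
        )
        if not ok.all():
            failures += 1
        else:
            rr, cc = cells[:, 0], cells[:, 1]
            if allowed[rr, cc].all() and not foreground[rr, cc].any():
                foreground[rr, cc] = True
                count += patch_area
                failures = 0
            else:
                failures += 1
        if failures >= max_failures:
            if target - count > patch_area:
                raise RuntimeError(
                    f"could not place enough disjoint patches: {count}/{target} px"
                )
            break
    image[foreground] = intensity
    return image, int(foreground.sum())


# ---------------------------------------------------------------------------
# 3D rendering


def render_nuclei_stack(
    spec: NucleiSpec,
    roi_pp: PolygonROI,
    roi_dp: PolygonROI,
    seed: int = 0,
    channel_names: tuple[str, str, str] = ("dapi", "dl", "drs"),
    max_failures: int = 5000,
) -> tuple[CalibratedImage, pd.DataFrame, np.ndarray]:
    """Render a 3-channel z-stack of non-overlapping ellipsoidal nuclei.

    Nuclei centers are rejection-sampled so that each (x, y) centroid lies
    in its compartment polygon and the whole ellipsoid fits in the volume
    without touching another nucleus (voxel-exact check).  Physical radii
    are drawn uniformly within ``radius_um ± radius_spread_um``; semi-axes
    in voxels follow from the anisotropic voxel size.

    Returns ``(stack, truth, labels)``: the calibrated image, a per-nucleus
    ground-truth table (center, radius, voxel count, volume, compartment,
    drawn and rendered channel totals), and the true label volume.
    """
    nz, ny, nx = spec.stack_shape
    dz, dy, dx = spec.voxel_size_um
    rng_place = _substream(seed, "placement")
    rng_int = _substream(seed, "intensity")
    rng_noise = _substream(seed, "noise")

    labels = np.zeros(spec.stack_shape, dtype=np.int32)
    dapi = np.full(spec.stack_shape, spec.dapi_background, dtype=np.float64)
    ch_a = np.zeros(spec.stack_shape, dtype=np.float64)
    ch_b = np.zeros(spec.stack_shape, dtype=np.float64)

    plan = [("PP", roi_pp, spec.n_proximal, spec.radius_um_proximal)] + [
        ("DP", roi_dp, spec.n_distal, spec.radius_um_distal)
    ]
    records: list[dict] = []
    label = 0
    for comp, roi, n, r_um in plan:
        xmin, ymin, xmax, ymax = roi.bounds()
        failures = 0
        placed = 0
        while placed < n:
            if failures >= max_failures:
                raise RuntimeError(
                    f"could not place {n} non-overlapping nuclei in {comp} "
                    f"(placed {placed})"
                )
            radius = rng_place.uniform(r_um - spec.radius_spread_um, r_um + spec.radius_spread_um)
            rz, ry, rx = radius / dz, radius / dy, radius / dx
            cx = rng_place.uniform(xmin, xmax)
            cy = rng_place.uniform(ymin, ymax)
            cz = rng_place.uniform(rz, nz - 1 - rz)
            if not points_in_polygon(np.array([[cx, cy]]), roi.vertices)[0]:
                failures += 1
                continue
            if (
                cx - rx < 0 or cx + rx > nx - 1 or cy - ry < 0 or cy + ry > ny - 1
            ):
                failures += 1
                continue
            # reject if any already-placed voxel lies within a 2-voxel halo:
            # keeps nuclei separated even under 26-connectivity
            halo = _ellipsoid_voxels(
                (cz, cy, cx), (rz + 2, ry + 2, rx + 2), spec.stack_shape
            )
            if labels[halo].any():
                failures += 1
                continue
            vox = _ellipsoid_voxels((cz, cy, cx), (rz, ry, rx), spec.stack_shape)
            label += 1
            labels[vox] = label
            dapi[vox] = spec.dapi_intensity
            # per-nucleus marker totals: bivariate normal on log10 scale
            la, lb = _bivariate_log_draw(rng_int, spec)
            total_a, total_b = 10.0**la, 10.0**lb
            n_vox = int(vox[0].size)
            ch_a[vox] = total_a / n_vox
            ch_b[vox] = total_b / n_vox
            records.append(
                dict(
                    label=label,
                    compartment=comp,
                    x=cx,
                    y=cy,
                    z=cz,
                    radius_um=radius,
                    voxel_count=n_vox,
                    volume_um3=n_vox * dz * dy * dx,
                    log10_total_a=la,
                    log10_total_b=lb,
                    total_a_drawn=total_a,
                    total_b_drawn=total_b,
                    total_a_rendered=float(ch_a[vox].sum()),
                    total_b_rendered=float(ch_b[vox].sum()),
                )
            )
            placed += 1
            failures = 0

    stack = np.stack([dapi, ch_a, ch_b]).astype(np.float64)
    if spec.gaussian_sigma > 0:
        stack = stack + rng_noise.normal(0, spec.gaussian_sigma, stack.shape)
    image = CalibratedImage(
        data=stack.astype(np.float32),
        pixel_size_um=spec.voxel_size_um,
        channels=list(channel_names),
    )
    truth = pd.DataFrame.from_records(records)
    return image, truth, labels


def _ellipsoid_voxels(
    center_zyx: tuple[float, float, float],
    radii_zyx: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, ...]:
    """Indices of voxels whose centers lie within the axis-aligned ellipsoid."""
    cz, cy, cx = center_zyx
    rz, ry, rx = radii_zyx
    z0, z1 = max(int(np.floor(cz - rz)), 0), min(int(np.ceil(cz + rz)) + 1, shape[0])
    y0, y1 = max(int(np.floor(cy - ry)), 0), min(int(np.ceil(cy + ry)) + 1, shape[1])
    x0, x1 = max(int(np.floor(cx - rx)), 0), min(int(np.ceil(cx + rx)) + 1, shape[2])
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    inside = (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0
    return zz[inside], yy[inside], xx[inside]


def _bivariate_log_draw(rng: np.random.Generator, spec: NucleiSpec) -> tuple[float, float]:
    mu_a, mu_b = spec.channel_log_means
    sd_a, sd_b = spec.channel_log_sds
    rho = spec.channel_log_correlation
    za = rng.standard_normal()
    zb = rng.standard_normal()
    la = mu_a + sd_a * za
    lb = mu_b + sd_b * (rho * za + np.sqrt(max(0.0, 1.0 - rho**2)) * zb)
    return float(la), float(lb)


def _substream(seed: int, purpose: str) -> np.random.Generator:
    """Deterministic named sub-stream of a single integer seed."""
    tag = int.from_bytes(purpose.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
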