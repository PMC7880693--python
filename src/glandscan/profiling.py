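"""Axial fluorescence profiling along a gland's Feret axis.

The gland's longitudinal axis is its Feret axis: the vertex pair of the
outline polygon attaining the maximum caliper distance.  To profile a
channel along that axis the image and gland mask are rotated so the axis
becomes horizontal (bilinear interpolation for intensities, nearest
neighbor for the mask), and the mean in-mask intensity of each 1-px column
slab is recorded.  This is equivalent to sweeping 1-px rectangular line
regions perpendicular to the axis, but easier to verify.

Because bilinear interpolation blends boundary pixels with the image
background, the rotated mask is eroded by ``erode_margin`` pixels (default
1) before column means are taken; columns left without in-mask pixels are
dropped and recorded.

Profiles from many glands are pooled by mapping positions to the relative
axis coordinate ``position / axis_length ∈ [0, 1]``, binning (default 256
bins), optionally normalizing each gland by its own mean intensity first,
and smoothing the cross-gland per-bin mean with a degree-2 tricube loess
(default span 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .io import CalibratedImage, PolygonROI, rasterize

__all__ = [
    "FeretAxis",
    "AxialProfile",
    "BinnedProfile",
    "feret_axis",
    "profile_along_axis",
    "normalize_profile",
    "bin_and_aggregate",
    "loess_smooth",
]


@dataclass(frozen=True)
class FeretAxis:
    """Maximum caliper (Feret) diameter and orientation of a polygon."""

    length_px: float
    angle_deg: float  # in (−90, 90], from +x axis, y pointing down
    endpoints: tuple[tuple[float, float], tuple[float, float]]


@dataclass
class AxialProfile:
    """Per-gland mean intensity vs. integer position along the Feret axis."""

    gland_id: str
    channel: str
    positions: np.ndarray  # integer px offsets, position 0 at proximal end
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    axis_length_px: float
    oriented: bool
    dropped_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.n_pixels < 1):
            raise ValueError("every reported position needs at least one pixel")


@dataclass
class BinnedProfile:
    """Cross-gland aggregate on a relative-position grid."""

    n_bins: int
    bin_centers: np.ndarray
    mean: np.ndarray  # cross-gland mean per bin (NaN where no gland)
    sd: np.ndarray
    n_glands: np.ndarray
    n_pixels: np.ndarray  # summed pixel support per bin
    smoothed: np.ndarray | None = None
    loess_span: float | None = None
    loess_degree: int | None = None
    normalization: str = "per-gland-mean"


# ---------------------------------------------------------------------------
# Feret axis


def feret_axis(roi: PolygonROI) -> FeretAxis:
    """Feret diameter and angle of a polygon ROI.

    The maximum pairwise vertex distance is attained on the convex hull, so
    only hull vertices are scanned; the result is exactly the brute-force
    maximum over all vertex pairs.  The angle of the attaining segment is
    mapped to (−90, 90] degrees.
    """
    verts = np.asarray(roi.vertices, dtype=float)
    if np.allclose(verts, verts[0]):
        raise ValueError("degenerate polygon: all vertices identical")
    try:
        hull = verts[ConvexHull(verts).vertices]
    except QhullError:  # collinear input: fall back to all vertices
        hull = verts
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    p, q = hull[i], hull[j]
    dx, dy = q - p
    angle = np.degrees(np.arctan2(dy, dx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return FeretAxis(
        length_px=float(np.sqrt(d2[i, j])),
        angle_deg=float(angle),
        endpoints=(tuple(p), tuple(q)),
    )


# ---------------------------------------------------------------------------
# rotation helper


def _rotation_transform(
    shape: tuple[int, int], angle_deg: float
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Forward map p' = R(−angle)·p + t that makes features at ``angle``
    horizontal, plus the output shape covering the rotated frame.

    Returns ``(rot, t, out_shape)`` with ``rot`` acting on (x, y) columns.
    """
    theta = np.deg2rad(-angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rows, cols = shape
    # map the pixel-center extent so that a zero angle is the exact identity
    corners = np.array(
        [[0.0, 0.0], [cols - 1.0, 0.0], [cols - 1.0, rows - 1.0], [0.0, rows - 1.0]]
    )
    rc = corners @ rot.T
    mins = rc.min(axis=0)
    maxs = rc.max(axis=0)
    t = -mins
    out_cols = int(np.floor(maxs[0] - mins[0])) + 1
    out_rows = int(np.floor(maxs[1] - mins[1])) + 1
    return rot, t, (out_rows, out_cols)


def _rotate_array(
    array: np.ndarray,
    rot: np.ndarray,
    t: np.ndarray,
    out_shape: tuple[int, int],
    order: int,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``array`` under the forward map p' = rot·p + t."""
    inv = rot.T  # rotation inverse
    # affine_transform maps output index (row, col) -> input index:
    # p_in(x,y) = inv @ (p_out - t)
    matrix = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset = -matrix @ np.array([t[1], t[0]])
    return ndimage.affine_transform(
        array.astype(float),
        matrix,
        offset=offset,
        output_shape=out_shape,
        order=order,
        cval=cval,
        prefilter=False,
    )


# ---------------------------------------------------------------------------
# profiling


def profile_along_axis(
    image: CalibratedImage,
    roi: PolygonROI,
    channel: str,
    anchor: tuple[float, float] | None = None,
    erode_margin: int = 1,
    gland_id: str = "gland",
) -> AxialProfile:
    """Mean in-mask intensity of each 1-px column slab along the Feret axis.

    ``anchor`` (default: the ROI's own anchor) marks the proximal tip;
    position 0 is the axis end nearest to it.  Without an anchor the
    profile is returned unoriented.
    """
    if image.is_stack:
        raise ValueError("profile_along_axis expects a 2D multichannel image")
    chan = image.channel(channel)
    mask = rasterize(roi, chan.shape)
    if not mask.any():
        raise ValueError("empty gland mask")
    axis = feret_axis(roi)
    rot, t, out_shape = _rotation_transform(chan.shape, axis.angle_deg)

    chan_rot = _rotate_array(chan, rot, t, out_shape, order=1)
    mask_rot = _rotate_array(mask.astype(np.uint8), rot, t, out_shape, order=0) > 0.5
    if erode_margin > 0:
        structure = ndimage.generate_binary_structure(2, 1)
        mask_rot = ndimage.binary_erosion(mask_rot, structure, iterations=erode_margin)
    if not mask_rot.any():
        raise ValueError("mask vanished after boundary erosion")

    counts = mask_rot.sum(axis=0)
    sums = np.where(mask_rot, chan_rot, 0.0).sum(axis=0)
    cols = np.flatnonzero(counts)
    first, last = cols[0], cols[-1]
    span = np.arange(first, last + 1)
    dropped = [int(c - first) for c in span[counts[span] == 0]]
    keep = counts[span] > 0
    positions = (span - first)[keep]
    means = sums[span][keep] / counts[span][keep]

    oriented = False
    if anchor is None:
        anchor = roi.anchor
    if anchor is not None:
        a_rot = rot @ np.asarray(anchor, dtype=float) + t
        if abs(a_rot[0] - last) < abs(a_rot[0] - first):
            positions = (last - first) - positions[::-1]
            means = means[::-1]
            counts_keep = counts[span][keep][::-1]
        else:
            counts_keep = counts[span][keep]
        oriented = True
    else:
        counts_keep = counts[span][keep]

    return AxialProfile(
        gland_id=gland_id,
        channel=channel,
        positions=positions.astype(int),
        mean_intensity=means,
        n_pixels=counts_keep.astype(int),
        axis_length_px=axis.length_px,
        oriented=oriented,
        dropped_positions=dropped,
    )


def normalize_profile(
    signal: AxialProfile, reference: AxialProfile, epsilon: float | None = None
) -> AxialProfile:
    """Pointwise ratio signal/(reference + ε) on a shared position grid.

    Emulates normalizing a reporter signal by a driver-independent
    counterstain.  ε defaults to 1e−6 of the reference maximum, so
    zero-reference positions stay finite; their indices are recorded in
    ``dropped_positions`` for inspection.
    """
    if not np.array_equal(signal.positions, reference.positions):
        raise ValueError("signal and reference profiles use different position grids")
    if signal.gland_id != reference.gland_id:
        raise ValueError("signal and reference come from different glands")
    if epsilon is None:
        epsilon = 1e-6 * float(np.max(reference.mean_intensity))
    ref = reference.mean_intensity
    flagged = [int(p) for p in signal.positions[ref <= 0]]
    ratio = signal.mean_intensity / (ref + epsilon)
    return AxialProfile(
        gland_id=signal.gland_id,
        channel=f"{signal.channel}/{reference.channel}",
        positions=signal.positions.copy(),
        mean_intensity=ratio,
        n_pixels=signal.n_pixels.copy(),
        axis_length_px=signal.axis_length_px,
        oriented=signal.oriented,
        dropped_positions=flagged,
    )


def bin_and_aggregate(
    profiles: list[AxialProfile],
    n_bins: int = 256,
    normalization: str = "per-gland-mean",
    span: float = 0.05,
    degree: int = 2,
    smooth: bool = True,
) -> BinnedProfile:
    """Bin per-gland profiles on the relative axis and average across glands.

    Each position maps to ``position / axis_length ∈ [0, 1]``.  Under
    ``per-gland-mean`` normalization each gland's intensities are divided by
    their own (unweighted) mean before pooling, so every normalized gland
    profile averages to 1 and glands contribute shape, not brightness.
    The cross-gland per-bin mean is loess-smoothed on the same grid.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if normalization not in ("per-gland-mean", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if any(not p.oriented for p in profiles) and any(p.oriented for p in profiles):
        raise ValueError("cannot mix oriented and unoriented profiles")

    centers = (np.arange(n_bins) + 0.5) / n_bins
    per_gland = np.full((len(profiles), n_bins), np.nan)
    pix = np.zeros(n_bins)
    for g, prof in enumerate(profiles):
        values = prof.mean_intensity
        if normalization == "per-gland-mean":
            values = values / values.mean()
        rel = prof.positions / prof.axis_length_px
        idx = np.clip((rel * n_bins).astype(int), 0, n_bins - 1)
        sums = np.bincount(idx, weights=values, minlength=n_bins)
        cnts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            per_gland[g] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        pix += np.bincount(idx, weights=prof.n_pixels, minlength=n_bins)

    n_glands = np.sum(~np.isnan(per_gland), axis=0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_gland, axis=0)
        sd = np.full(n_bins, np.nan)
        multi = n_glands > 1
        if multi.any():
            sd[multi] = np.nanstd(per_gland[:, multi], axis=0, ddof=1)

    smoothed = None
    if smooth:
        good = n_glands > 0
        smoothed = np.full(n_bins, np.nan)
        if good.sum() > degree + 1:
            smoothed[good] = loess_smooth(centers[good], mean[good], span=span, degree=degree)

    return BinnedProfile(
        n_bins=n_bins,
        bin_centers=centers,
        mean=mean,
        sd=sd,
        n_glands=n_glands,
        n_pixels=pix,
        smoothed=smoothed,
        loess_span=span if smooth else None,
        loess_degree=degree if smooth else None,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# loess


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float = 0.05, degree: int = 2
) -> np.ndarray:
    """Locally weighted polynomial regression (loess) on the same grid.

    For each grid point the ``ceil(span·n)`` nearest neighbors are fit with
    a degree-``degree`` polynomial under tricube weights
    ``(1 − (d/d_max)³)³``; no robustness iterations.  Raises ``ValueError``
    (naming the grid point) if a window has fewer than ``degree + 1``
    points with positive weight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    n = len(x)
    k = int(np.ceil(span * n))
    out = np.empty(n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for pos, xi in enumerate(x):
        d = np.abs(xs - xi)
        nn = np.argpartition(d, min(k - 1, n - 1))[:k]
        dmax = d[nn].max()
        if dmax == 0:
            w = np.ones(len(nn))
        else:
            w = (1 - (d[nn] / dmax) ** 3) ** 3
        pos_w = w > 0
        if pos_w.sum() < degree + 1:
            raise ValueError(
                f"loess window at x={xi:g} is rank-deficient "
                f"({int(pos_w.sum())} weighted points for degree {degree}); "
                "increase span"
            )
        xc = xs[nn] - xi
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ys[nn] * sw, rcond=None)
        out[pos] = coef[0]
    return out
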