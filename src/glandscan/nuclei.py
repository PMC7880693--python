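"""3D nuclear segmentation and volume morphometry.

Nuclei are segmented from the DAPI channel of a z-stack by global
thresholding, labeled as connected components (26-connectivity by default,
the convention of the classic 3D object counters), measured as calibrated
volumes (voxel count × voxel volume) and assigned to the proximal or distal
gland compartment by a 2D point-in-polygon test of their (x, y) centroid —
one hand-drawn 2D ROI is shared by all slices of a stack, so z is ignored.

Gland-level summaries average nuclear volume per gland (optionally per
compartment); hypertrophy between cohorts is reported as the fold-change of
those means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import PolygonROI, points_in_polygon

__all__ = [
    "NucleusRecord",
    "GlandNucleiSummary",
    "threshold_stack",
    "label_components",
    "measure_nuclei",
    "accumulate_intensity",
    "assign_compartments",
    "summarize_gland",
    "fold_change",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus."""

    label: int
    voxel_count: int
    volume_um3: float
    centroid: tuple[float, float, float]  # (x, y, z) in voxel units
    compartment: str = "unassigned"  # PP | DP | unassigned
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass
class GlandNucleiSummary:
    gland_id: str
    n_total: int
    mean_volume_um3: float
    n_pp: int = 0
    n_dp: int = 0
    n_unassigned: int = 0
    mean_volume_pp_um3: float | None = None
    mean_volume_dp_um3: float | None = None


def threshold_stack(
    stack: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    value: float | None = None,
) -> np.ndarray:
    """Global threshold of a single-channel 3D stack; foreground = above.

    ``otsu`` computes the between-class-variance-maximizing threshold on a
    256-bin histogram of the full data range; ``fixed`` uses ``value``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a single-channel 3D stack, got {stack.ndim} axes")
    if method == "otsu":
        if np.ptp(stack) == 0:
            raise ValueError("cannot Otsu-threshold a constant stack")
        thr = threshold_otsu(stack, nbins=256)
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = value
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return stack > thr


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def label_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label maximal connected foreground components 1..K."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 26 or 6")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("expected a binary 3D array")
    labels, _ = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return labels


def measure_nuclei(
    labels: np.ndarray,
    voxel_size_um: Sequence[float],
    min_size_voxels: int = 64,
    intensity_channels: dict[str, np.ndarray] | None = None,
) -> tuple[list[NucleusRecord], dict]:
    """Per-component voxel counts, calibrated volumes and centroids.

    Components below ``min_size_voxels`` are dropped and counted in the
    returned QC dict (``n_dropped``, ``dropped_voxels``), so the voxel total
    over retained + dropped components always equals the foreground count.
    Optional intensity channels are summed per nucleus (accumulated
    intensity).
    """
    labels = np.asarray(labels)
    dz, dy, dx = (float(v) for v in voxel_size_um)
    voxel_volume = dz * dy * dx
    n_labels = int(labels.max())
    qc = {"n_dropped": 0, "dropped_voxels": 0, "n_labels": n_labels}
    if n_labels == 0:
        return [], qc

    counts = np.bincount(labels.ravel(), minlength=n_labels + 1)
    sums = {}
    if intensity_channels:
        for name, chan in intensity_channels.items():
            chan = np.asarray(chan)
            if chan.shape != labels.shape:
                raise ValueError(f"channel {name!r} shape differs from labels")
            sums[name] = accumulate_intensity(labels, chan)

    # unweighted centroids for all labels at once
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in labels.shape), indexing="ij")
    flat = labels.ravel()
    cz = np.bincount(flat, weights=zz.ravel(), minlength=n_labels + 1)
    cy = np.bincount(flat, weights=yy.ravel(), minlength=n_labels + 1)
    cx = np.bincount(flat, weights=xx.ravel(), minlength=n_labels + 1)

    records = []
    for lab in range(1, n_labels + 1):
        n_vox = int(counts[lab])
        if n_vox == 0:
            continue
        if n_vox < min_size_voxels:
            qc["n_dropped"] += 1
            qc["dropped_voxels"] += n_vox
            continue
        records.append(
            NucleusRecord(
                label=lab,
                voxel_count=n_vox,
                volume_um3=n_vox * voxel_volume,
                centroid=(cx[lab] / n_vox, cy[lab] / n_vox, cz[lab] / n_vox),
                intensities={name: float(s[lab]) for name, s in sums.items()},
            )
        )
    return records, qc


def accumulate_intensity(labels: np.ndarray, channel: np.ndarray) -> np.ndarray:
    """Sum of channel intensity over each label's voxels.

    Returns an array indexed by label (index 0 = background).
    """
    labels = np.asarray(labels)
    channel = np.asarray(channel)
    if labels.shape != channel.shape:
        raise ValueError(
            f"labels shape {labels.shape} != channel shape {channel.shape}"
        )
    return np.bincount(
        labels.ravel(), weights=channel.ravel().astype(np.float64),
        minlength=int(labels.max()) + 1,
    )


def assign_compartments(
    records: Iterable[NucleusRecord],
    roi_pp: PolygonROI,
    roi_dp: PolygonROI,
) -> list[NucleusRecord]:
    """Set each record's compartment from its (x, y) centroid (z ignored).

    The proximal and distal polygons must not overlap; a nucleus whose
    centroid falls in neither stays ``unassigned``.
    """
    inter = roi_pp.shapely.intersection(roi_dp.shapely).area
    if inter > 1e-6 * min(roi_pp.area, roi_dp.area):
        raise ValueError("proximal and distal ROIs overlap")
    records = list(records)
    if not records:
        return records
    pts = np.array([[r.centroid[0], r.centroid[1]] for r in records])
    in_pp = points_in_polygon(pts, roi_pp.vertices)
    in_dp = points_in_polygon(pts, roi_dp.vertices)
    for rec, pp, dp in zip(records, in_pp, in_dp):
        rec.compartment = "PP" if pp else ("DP" if dp else "unassigned")
    return records


def summarize_gland(
    records: Sequence[NucleusRecord],
    gland_id: str = "gland",
    per_compartment: bool = True,
) -> GlandNucleiSummary:
    """Arithmetic mean nuclear volume over one gland's nuclei.

    An empty compartment yields a missing (None) per-compartment mean.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize a gland without nuclei")
    vols = np.array([r.volume_um3 for r in records])
    summary = GlandNucleiSummary(
        gland_id=gland_id,
        n_total=len(records),
        mean_volume_um3=float(vols.mean()),
    )
    if per_compartment:
        for comp, attr_n, attr_m in (
            ("PP", "n_pp", "mean_volume_pp_um3"),
            ("DP", "n_dp", "mean_volume_dp_um3"),
        ):
            sel = [r.volume_um3 for r in records if r.compartment == comp]
            setattr(summary, attr_n, len(sel))
            if sel:
                setattr(summary, attr_m, float(np.mean(sel)))
        summary.n_unassigned = sum(r.compartment == "unassigned" for r in records)
    return summary


def fold_change(
    group_means: Sequence[float], control_means: Sequence[float]
) -> float:
    """mean(group) / mean(control) of per-gland mean volumes."""
    group = np.asarray(group_means, dtype=float)
    control = np.asarray(control_means, dtype=float)
    if group.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    cm = control.mean()
    if cm <= 0:
        raise ValueError("control mean must be positive")
    return float(group.mean() / cm)
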