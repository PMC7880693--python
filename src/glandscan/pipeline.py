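"""End-to-end study orchestration: simulate → measure → test.

``simulate_study`` writes a complete mock two-cohort study to disk (images,
z-stacks, ROIs, calibration sidecars, ground truth, manifest);
``analyze_study`` runs every analysis stage over a manifest and writes tidy
CSV tables plus a JSON report; ``run_study`` chains the two.  Every output
row carries the gland id, genotype, timepoint, the master seed and a short
hash of the configuration, and re-running with the same config and seed
reproduces the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attachment import attachment_statistic, effect_size, segment_marker_area
from .correlation import correlate_channels
from .io import CalibratedImage, read_image, read_roi, write_image, write_roi
from .nuclei import (
    assign_compartments,
    fold_change,
    label_components,
    measure_nuclei,
    summarize_gland,
    threshold_stack,
)
from .profiling import bin_and_aggregate, normalize_profile, profile_along_axis
from .synthetic import (
    ChannelProfile,
    GlandSpec,
    NucleiSpec,
    ProfileSpec,
    make_gland_roi,
    render_gland_image,
    render_hemocyte_channel,
    render_nuclei_stack,
)

logger = logging.getLogger(__name__)

__all__ = ["default_study_config", "simulate_study", "analyze_study", "run_study"]

_FLOAT_FMT = "%.9g"


def default_study_config() -> dict[str, Any]:
    """The shipped demo study: a control and a hypertrophic cohort.

    The hypertrophic cohort's nuclear radius is scaled by the cube root of
    ``volume_fold`` (default 5.66, a published whole-gland fold-change used
    here as a simulation setting), its hemocyte coverage is raised and
    restricted to the distal part, and the reporter gradient runs
    proximal-high to distal-low.
    """
    return {
        "timepoint": "120h",
        "n_glands": 5,
        "volume_fold": 5.66,
        "image": {
            "shape": [140, 200],
            "gland_length_px": 150,
            "gland_width_px": 36,
            "rotations_deg": [0.0, 10.0, 20.0, 30.0, 40.0],
            "bend_amplitude_px": 0.0,
            "pixel_size_um": 0.65,
        },
        "stack": {
            "shape": [24, 110, 160],
            "gland_length_px": 140,
            "gland_width_px": 60,
            "voxel_size_um": [1.0, 0.5, 0.5],
            "n_proximal": 12,
            "n_distal": 12,
        },
        "hemocyte": {
            "patch_radius_px": 4.0,
            "threshold": 100.0,
            "intensity": 200.0,
        },
        "profile": {"n_bins": 128, "loess_span": 0.05, "loess_degree": 2},
        "nuclei": {"threshold": "otsu", "min_size_voxels": 64, "connectivity": 26},
        "cohorts": {
            "control": {
                "nuclear_radius_um": 2.3,
                "hemocyte_fraction": 0.02,
                "hemocyte_restrict_to": "whole",
                "reporter": {"kind": "linear", "params": [150.0, -100.0]},
                "phalloidin_level": 120.0,
                "channel_log_correlation": 0.8,
            },
            "hypertrophic": {
                "nuclear_radius_um": None,  # control radius × volume_fold^(1/3)
                "hemocyte_fraction": 0.10,
                "hemocyte_restrict_to": "DP",
                "reporter": {"kind": "linear", "params": [150.0, -100.0]},
                "phalloidin_level": 120.0,
                "channel_log_correlation": 0.8,
            },
        },
    }


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def _gland_seed(master_seed: int, cohort: str, index: int, purpose: str) -> int:
    h = hashlib.sha256(f"{master_seed}/{cohort}/{index}/{purpose}".encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def _cohort_radius(config: dict, cohort: str) -> float:
    r = config["cohorts"][cohort]["nuclear_radius_um"]
    if r is None:
        base = config["cohorts"]["control"]["nuclear_radius_um"]
        r = base * config["volume_fold"] ** (1.0 / 3.0)
    return float(r)


# ---------------------------------------------------------------------------
# simulation


def simulate_study(
    config: dict | None, outdir: str | Path, seed: int = 0
) -> dict[str, Any]:
    """Generate the full synthetic study on disk and return the manifest."""
    config = config or default_study_config()
    outdir = Path(outdir)
    data_dir = outdir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)

    img_cfg = config["image"]
    stk_cfg = config["stack"]
    hem_cfg = config["hemocyte"]
    glands = []
    for cohort, ccfg in config["cohorts"].items():
        radius = _cohort_radius(config, cohort)
        for i in range(config["n_glands"]):
            gid = f"{cohort}_{i:02d}"
            rot = img_cfg["rotations_deg"][i % len(img_cfg["rotations_deg"])]
            gspec = GlandSpec(
                length_px=img_cfg["gland_length_px"],
                width_px=img_cfg["gland_width_px"],
                rotation_deg=rot,
                bend_amplitude_px=img_cfg.get("bend_amplitude_px", 0.0),
                image_shape=tuple(img_cfg["shape"]),
                pixel_size_um=img_cfg["pixel_size_um"],
            )
            geom = make_gland_roi(gspec)
            rep = ccfg["reporter"]
            pspec = ProfileSpec(
                channels={
                    "drs": ChannelProfile(rep["kind"], tuple(rep["params"])),
                    "phalloidin": ChannelProfile(
                        "constant", (ccfg["phalloidin_level"],)
                    ),
                }
            )
            image, truth2d = render_gland_image(
                geom, pspec, seed=_gland_seed(seed, cohort, i, "image")
            )
            hem, hem_count = render_hemocyte_channel(
                geom,
                target_fraction=ccfg["hemocyte_fraction"],
                patch_radius_px=hem_cfg["patch_radius_px"],
                restrict_to=ccfg.get("hemocyte_restrict_to", "whole"),
                seed=_gland_seed(seed, cohort, i, "hemocyte"),
                intensity=hem_cfg["intensity"],
            )
            full = CalibratedImage(
                data=np.concatenate([image.data, hem[None]], axis=0),
                pixel_size_um=image.pixel_size_um,
                channels=image.channels + ["hemese"],
            )
            img_path = data_dir / f"{gid}_image.tif"
            write_image(img_path, full)
            roi_paths = {}
            for tag, roi in (
                ("gland", geom.gland),
                ("pp", geom.proximal),
                ("dp", geom.distal),
            ):
                p = data_dir / f"{gid}_roi_{tag}.json"
                write_roi(p, roi)
                roi_paths[tag] = p.name

            # nuclei z-stack with its own (unrotated) gland geometry
            sspec_geom = GlandSpec(
                length_px=stk_cfg["gland_length_px"],
                width_px=stk_cfg["gland_width_px"],
                image_shape=tuple(stk_cfg["shape"][1:]),
                pixel_size_um=stk_cfg["voxel_size_um"][1],
            )
            sgeom = make_gland_roi(sspec_geom)
            nspec = NucleiSpec(
                n_proximal=stk_cfg["n_proximal"],
                n_distal=stk_cfg["n_distal"],
                radius_um_proximal=radius,
                radius_um_distal=radius,
                radius_spread_um=0.1 * radius,
                voxel_size_um=tuple(stk_cfg["voxel_size_um"]),
                stack_shape=tuple(stk_cfg["shape"]),
                channel_log_correlation=ccfg["channel_log_correlation"],
            )
            stack, ntruth, _labels = render_nuclei_stack(
                nspec,
                sgeom.proximal,
                sgeom.distal,
                seed=_gland_seed(seed, cohort, i, "stack"),
            )
            stack_path = data_dir / f"{gid}_stack.tif"
            write_image(stack_path, stack)
            stack_rois = {}
            for tag, roi in (("pp", sgeom.proximal), ("dp", sgeom.distal)):
                p = data_dir / f"{gid}_stack_roi_{tag}.json"
                write_roi(p, roi)
                stack_rois[tag] = p.name
            truth_path = data_dir / f"{gid}_nuclei_truth.csv"
            ntruth.to_csv(truth_path, index=False, float_format=_FLOAT_FMT)
            truth2d_path = data_dir / f"{gid}_truth.json"
            truth2d_path.write_text(
                json.dumps(
                    {
                        "seed": seed,
                        "gland_pixel_count": int(truth2d.mask.sum()),
                        "hemocyte_pixel_count": int(hem_count),
                        "profile_s": truth2d.profile_s.tolist(),
                        "profile_values": {
                            k: v.tolist() for k, v in truth2d.profile_values.items()
                        },
                    }
                )
            )
            glands.append(
                {
                    "id": gid,
                    "genotype": cohort,
                    "timepoint": config["timepoint"],
                    "image": img_path.name,
                    "rois": roi_paths,
                    "stack": stack_path.name,
                    "stack_rois": stack_rois,
                    "nuclei_truth": truth_path.name,
                    "truth": truth2d_path.name,
                }
            )

    manifest = {
        "seed": seed,
        "config_hash": chash,
        "glandscan_version": __version__,
        "config": config,
        "data_dir": "data",
        "glands": glands,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


# ---------------------------------------------------------------------------
# analysis


def _validate_manifest(manifest: dict, outdir: Path) -> Path:
    data_dir = outdir / manifest["data_dir"]
    missing = []
    for gland in manifest["glands"]:
        for key in ("image", "stack", "nuclei_truth"):
            if not (data_dir / gland[key]).exists():
                missing.append(gland[key])
        for group in ("rois", "stack_rois"):
            for p in gland[group].values():
                if not (data_dir / p).exists():
                    missing.append(p)
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")
    return data_dir


def analyze_study(manifest: dict, outdir: str | Path) -> dict[str, Any]:
    """Run profiling, nuclear morphometry, attachment, correlation and the
    statistical battery over a simulated (or equivalent) study."""
    outdir = Path(outdir)
    data_dir = _validate_manifest(manifest, outdir)
    results_dir = outdir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    config = manifest["config"]
    meta = {
        "seed": manifest["seed"],
        "config_hash": manifest["config_hash"],
    }
    t0 = time.time()
    report: dict[str, Any] = {
        "glandscan_version": __version__,
        **meta,
        "stages": {},
        "failures": [],
    }

    profiles_by_cohort: dict[str, list] = {}
    nuc_rows, summary_rows, attach_rows = [], [], []
    sums_by_cohort: dict[str, dict[str, list]] = {}

    for gland in manifest["glands"]:
        gid, cohort, tp = gland["id"], gland["genotype"], gland["timepoint"]
        try:
            image = read_image(data_dir / gland["image"])
            roi = read_roi(data_dir / gland["rois"]["gland"])
            roi_pp = read_roi(data_dir / gland["rois"]["pp"])
            roi_dp = read_roi(data_dir / gland["rois"]["dp"])

            # --- axial profile, reporter normalized by counterstain
            sig = profile_along_axis(image, roi, "drs", gland_id=gid)
            ref = profile_along_axis(image, roi, "phalloidin", gland_id=gid)
            profiles_by_cohort.setdefault(cohort, []).append(
                normalize_profile(sig, ref)
            )

            # --- hemocyte attachment, whole gland and per compartment
            from .io import rasterize  # local to avoid cycle at import time

            hem = image.channel("hemese")
            thr = config["hemocyte"]["threshold"]
            for comp, comp_roi in (
                ("whole", roi),
                ("PP", roi_pp),
                ("DP", roi_dp),
            ):
                mask = rasterize(comp_roi, hem.shape)
                area = int(mask.sum())
                hem_area = segment_marker_area(hem, thr, roi_mask=mask)
                attach_rows.append(
                    {
                        "gland_id": gid,
                        "genotype": cohort,
                        "timepoint": tp,
                        "compartment": comp,
                        "hemocyte_area_px": hem_area,
                        "gland_area_px2": area,
                        "statistic": attachment_statistic(hem_area, area),
                        **meta,
                    }
                )

            # --- nuclei
            stack = read_image(data_dir / gland["stack"])
            s_pp = read_roi(data_dir / gland["stack_rois"]["pp"])
            s_dp = read_roi(data_dir / gland["stack_rois"]["dp"])
            ncfg = config["nuclei"]
            mask3 = threshold_stack(stack.channel("dapi"), method=ncfg["threshold"])
            labels = label_components(mask3, connectivity=ncfg["connectivity"])
            records, qc = measure_nuclei(
                labels,
                stack.pixel_size_um,
                min_size_voxels=ncfg["min_size_voxels"],
                intensity_channels={
                    "dl": stack.channel("dl"),
                    "drs": stack.channel("drs"),
                },
            )
            records = assign_compartments(records, s_pp, s_dp)
            summary = summarize_gland(records, gland_id=gid)
            summary_rows.append(
                {
                    "gland_id": gid,
                    "genotype": cohort,
                    "timepoint": tp,
                    "n_nuclei": summary.n_total,
                    "mean_volume_um3": summary.mean_volume_um3,
                    "n_pp": summary.n_pp,
                    "n_dp": summary.n_dp,
                    "mean_volume_pp_um3": summary.mean_volume_pp_um3,
                    "mean_volume_dp_um3": summary.mean_volume_dp_um3,
                    "n_dropped_qc": qc["n_dropped"],
                    **meta,
                }
            )
            cs = sums_by_cohort.setdefault(
                cohort, {"a": [], "b": [], "comp": []}
            )
            for rec in records:
                nuc_rows.append(
                    {
                        "gland_id": gid,
                        "genotype": cohort,
                        "timepoint": tp,
                        "label": rec.label,
                        "compartment": rec.compartment,
                        "voxel_count": rec.voxel_count,
                        "volume_um3": rec.volume_um3,
                        "x": rec.centroid[0],
                        "y": rec.centroid[1],
                        "z": rec.centroid[2],
                        "sum_dl": rec.intensities["dl"],
                        "sum_drs": rec.intensities["drs"],
                        **meta,
                    }
                )
                cs["a"].append(rec.intensities["dl"])
                cs["b"].append(rec.intensities["drs"])
                cs["comp"].append(rec.compartment)
        except Exception as exc:  # per-gland failures are logged, never silent
            logger.exception("gland %s failed", gid)
            report["failures"].append({"gland_id": gid, "error": str(exc)})

    # --- cross-gland aggregates
    pcfg = config["profile"]
    binned_rows = []
    for cohort, profs in profiles_by_cohort.items():
        binned = bin_and_aggregate(
            profs,
            n_bins=pcfg["n_bins"],
            span=pcfg["loess_span"],
            degree=pcfg["loess_degree"],
        )
        for i in range(binned.n_bins):
            if binned.n_glands[i] == 0:
                continue
            binned_rows.append(
                {
                    "genotype": cohort,
                    "bin_center": binned.bin_centers[i],
                    "mean": binned.mean[i],
                    "sd": binned.sd[i],
                    "n_glands": int(binned.n_glands[i]),
                    "smoothed": binned.smoothed[i],
                    **meta,
                }
            )

    corr_rows = []
    for cohort, cs in sums_by_cohort.items():
        res = correlate_channels(
            np.array(cs["a"]), np.array(cs["b"]), compartments=np.array(cs["comp"])
        )
        for comp, cr in res.items():
            corr_rows.append(
                {
                    "genotype": cohort,
                    "compartment": comp,
                    "n": cr.n,
                    "pearson_r": cr.pearson_r,
                    "slope": cr.slope,
                    "intercept": cr.intercept,
                    "n_excluded": cr.n_excluded,
                    **meta,
                }
            )

    # --- statistics battery
    from .stats import t_test_auto

    stats_rows = []
    summary_df = pd.DataFrame(summary_rows)
    attach_df = pd.DataFrame(attach_rows)
    cohorts = list(config["cohorts"])
    if len(cohorts) == 2 and not summary_df.empty:
        a, b = cohorts
        va = summary_df.loc[summary_df.genotype == a, "mean_volume_um3"].to_numpy()
        vb = summary_df.loc[summary_df.genotype == b, "mean_volume_um3"].to_numpy()
        if len(va) >= 2 and len(vb) >= 2:
            tr = t_test_auto(vb, va)
            stats_rows.append(
                {
                    "comparison": f"mean_nuclear_volume: {b} vs {a}",
                    "method": tr.method,
                    "statistic": tr.statistic,
                    "df": tr.df,
                    "p_value": tr.p_value,
                    "stars": tr.stars,
                    "fold_change": fold_change(vb, va),
                    **meta,
                }
            )
        wa = attach_df.query("genotype == @a and compartment == 'whole'")[
            "statistic"
        ].to_numpy()
        wb = attach_df.query("genotype == @b and compartment == 'whole'")[
            "statistic"
        ].to_numpy()
        if len(wa) >= 2 and len(wb) >= 2 and (np.ptp(wa) > 0 or np.ptp(wb) > 0):
            tr = t_test_auto(wb, wa)
            eff, ref = effect_size(wa, wb)  # second cohort anchored at 1
            stats_rows.append(
                {
                    "comparison": f"hemocyte_attachment: {b} vs {a}",
                    "method": tr.method,
                    "statistic": tr.statistic,
                    "df": tr.df,
                    "p_value": tr.p_value,
                    "stars": tr.stars,
                    "fold_change": float(np.mean(eff)),
                    **meta,
                }
            )

    tables = {
        "profiles.csv": pd.DataFrame(binned_rows),
        "nuclei.csv": pd.DataFrame(nuc_rows),
        "gland_summary.csv": summary_df,
        "attachment.csv": attach_df,
        "correlation.csv": pd.DataFrame(corr_rows),
        "stats.csv": pd.DataFrame(stats_rows),
    }
    for name, df in tables.items():
        df.to_csv(results_dir / name, index=False, float_format=_FLOAT_FMT)

    report["stages"] = {
        "profiles": len(binned_rows),
        "nuclei": len(nuc_rows),
        "gland_summaries": len(summary_rows),
        "attachment": len(attach_rows),
        "correlation": len(corr_rows),
        "stats": len(stats_rows),
    }
    report["runtime_s"] = round(time.time() - t0, 3)
    report["clean"] = not report["failures"]
    (results_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def run_study(
    config: dict | None = None, outdir: str | Path = "glandscan_run", seed: int = 0
) -> dict[str, Any]:
    """Simulate the study and run the full analysis over it."""
    manifest = simulate_study(config, outdir, seed=seed)
    return analyze_study(manifest, outdir)
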