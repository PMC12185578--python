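"""Two-stage analysis workflow: segment, then measure.

Stage 1 produces and validates tissue label masks (classifier or
supplied masks, plus optional polygon refinements) for each analysis
region.  Stage 2 — run only on regions whose epidermis band passes the
partition check — computes the depth field, detects DAB areas, pools
depth distributions per condition, runs the comparisons and writes
tables, figures and a reproducibility manifest.  The split lets an
operator validate segmentation before any measurement depends on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    CalibratedImage, LabelMask, SquareRegion,
    crop_region, crop_mask, read_image, read_label_mask, write_label_mask,
    write_float_map, _load_feature_collection, _round_half_up,
)
from .classify import PixelClassifierModel, classify_pixels, apply_refinement
from .topology import validate_partition, build_tissue_masks
from .depth import relative_depth
from .detect import DetectionParams, detect_dab_areas, attach_depths
from .stats import (
    pool_distribution, histogram, per_replicate_histograms,
    wilcoxon_compare, tertile_compare, ks_normality, results_table, violin_figure,
)

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def grid_regions(
    mask: LabelMask, side_um: float, max_regions: int = 5
) -> list[SquareRegion]:
    """Tile the image with squares and keep those passing the partition check.

    Deterministic row-major scan; at most ``max_regions`` regions are
    returned, mirroring the 3–5 squares an operator would place while
    avoiding folds and cuts.
    """
    um = mask.pixel_size_um
    side_px = _round_half_up(side_um / um)
    out: list[SquareRegion] = []
    for r0 in range(0, mask.shape[0] - side_px + 1, side_px):
        for c0 in range(0, mask.shape[1] - side_px + 1, side_px):
            region = SquareRegion(c0 * um, r0 * um, side_um)
            sub = crop_mask(mask, region)
            if validate_partition(sub).ok:
                out.append(region)
                if len(out) >= max_regions:
                    return out
    return out


def _region_list(cfg: dict, mask: LabelMask) -> list[SquareRegion]:
    rcfg = cfg.get("regions", {})
    if rcfg.get("mode", "grid") == "explicit":
        return [
            SquareRegion(r["origin_x_um"], r["origin_y_um"], r["side_um"])
            for r in rcfg["list"]
        ]
    return grid_regions(mask, rcfg.get("side_um", 500.0), rcfg.get("count", 5))


def segment_image(entry: dict, cfg: dict) -> tuple[CalibratedImage, LabelMask]:
    """Stage-1 work for one image entry: labels + optional refinement."""
    um = cfg.get("pixel_size_um")
    img = read_image(entry["path"], pixel_size_um=um)
    if "label_mask" in entry:
        mask = read_label_mask(entry["label_mask"], img.pixel_size_um, shape=img.shape)
    else:
        model = PixelClassifierModel.load(entry.get("classifier", cfg.get("classifier")))
        mask = classify_pixels(model, img)
    if "refinements" in entry:
        feats = _load_feature_collection(Path(entry["refinements"]))
        mask = apply_refinement(mask, feats)
    return img, mask


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run both stages for every image/region in the config.

    Returns the output directory.  Regions failing the partition check
    are recorded in ``failed_regions.json`` and skipped by stage 2; all
    other regions complete.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = DetectionParams.from_dict(
        {**DetectionParams().to_dict(), **config.get("detection", {})}
    )

    failed: list[dict] = []
    blob_rows: list[dict] = []
    dists_by_condition: dict[str, tuple[list, list]] = {}

    for i, entry in enumerate(config.get("images", [])):
        img, mask = segment_image(entry, config)
        condition = entry.get("condition", f"image{i}")
        stem = f"{i:02d}_{Path(entry['path']).stem}"
        write_label_mask(mask, out_dir / f"{stem}_labels.png")
        regions = _region_list(config, mask)
        for j, region in enumerate(regions):
            sub_mask = crop_mask(mask, region)
            report = validate_partition(sub_mask)
            if not report.ok:
                logger.warning("region %d of %s failed partition: %s",
                               j, entry["path"], "; ".join(report.reasons))
                failed.append({"image": entry["path"], "region": j, **report.to_dict()})
                continue
            masks = build_tissue_masks(sub_mask)
            field = relative_depth(masks, sub_mask)
            sub_img = crop_region(img, region)
            blobs = detect_dab_areas(sub_img, params)
            if abs(sub_img.pixel_size_um - params.pixel_size_um) > 1e-4 * params.pixel_size_um:
                raise ValueError(
                    "detection grid differs from segmentation grid; "
                    "provide images at the detection pixel size"
                )
            attach_depths(blobs, field)
            write_float_map(field.d_rel, out_dir / f"{stem}_r{j}_drel.tif",
                            field.pixel_size_um)
            for b in blobs:
                blob_rows.append({
                    "image": entry["path"], "condition": condition, "region": j,
                    "blob_id": b.id, "area_um2": b.area_um2,
                    "centroid_row": b.centroid[0], "centroid_col": b.centroid[1],
                    "mean_od_sum": b.mean_od_sum, "mean_d_rel": b.mean_d_rel,
                    "mean_dist_from_epi_um": b.mean_dist_from_epi_um,
                    "mean_dist_from_derm_um": b.mean_dist_from_derm_um,
                })
            lists = dists_by_condition.setdefault(condition, ([], []))
            lists[0].append(blobs)
            lists[1].append(field)

    dists = {
        cond: pool_distribution(blobs, fields, cond)
        for cond, (blobs, fields) in dists_by_condition.items()
    }

    pd.DataFrame(blob_rows).to_csv(out_dir / "blobs.csv", index=False)
    pixel_rows = []
    for cond, dist in dists.items():
        pixel_rows.append(pd.DataFrame({
            "condition": cond,
            "d_rel": dist.pixel_d_rel,
            "dist_from_epi_um": dist.pixel_dist_epi_um,
            "dist_from_derm_um": dist.pixel_dist_derm_um,
            "replicate": dist.replicate_of_pixel,
        }))
    (pd.concat(pixel_rows, ignore_index=True) if pixel_rows else pd.DataFrame(
        columns=["condition", "d_rel", "dist_from_epi_um", "dist_from_derm_um", "replicate"]
    )).to_csv(out_dir / "pixel_depths.csv", index=False)

    comparisons: dict[str, object] = {}
    for pair in config.get("compare", []):
        a_name, b_name = pair[0], pair[1]
        if a_name in dists and b_name in dists:
            a = dists[a_name].pixel_d_rel
            b = dists[b_name].pixel_d_rel
            if a.size and b.size:
                key = f"{a_name}_vs_{b_name}"
                comparisons[key] = wilcoxon_compare(a, b)
                comparisons[key + "_onesided"] = wilcoxon_compare(a, b, "greater")
                comparisons[key + "_tertiles"] = tertile_compare(a, b)
    if comparisons:
        results_table(comparisons).to_csv(out_dir / "comparisons.csv", index=False)

    normality_rows = [
        {"condition": cond, "n": d.n_pixels,
         "ks_normality_p": ks_normality(d.pixel_d_rel) if d.n_pixels >= 5 else np.nan}
        for cond, d in dists.items()
    ]
    pd.DataFrame(normality_rows).to_csv(out_dir / "normality.csv", index=False)

    nonempty = {c: d for c, d in dists.items() if d.n_pixels > 0}
    if nonempty:
        fig = violin_figure(nonempty)
        fig.savefig(out_dir / "violin.png", dpi=150)
        for cond, dist in nonempty.items():
            per_replicate_histograms(dist).to_csv(
                out_dir / f"hist_{cond}.csv", index=False
            )

    with open(out_dir / "failed_regions.json", "w") as fh:
        json.dump(failed, fh, indent=2)

    manifest = {
        "software": "dabdepth",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "detection_params": params.to_dict(),
        "tertile_definition": "depth bands [0,1/3),[1/3,2/3),[2/3,1] on d_rel",
        "n_images": len(config.get("images", [])),
        "n_failed_regions": len(failed),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir
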