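"""File-based orchestration of the full same-section analysis.

Each stage reads its inputs from, and writes its outputs to, a single
output directory, so stages can be run individually (CLI subcommands) or
chained by :func:`run_all`.  All stochastic stages derive their
randomness from the single configured seed, and every output is a plain
CSV/TIFF/GeoJSON/JSON file, so two runs with the same seed and config
produce byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import annotate, cluster, correlate, integrate, seg_compare, segment, simulate
from .core_io import (
    Frame,
    LabelMask,
    TranscriptTable,
    read_intensity_stack,
    read_label_mask,
    read_regions,
    read_transcripts,
    write_cell_table,
    write_intensity_stack,
    write_label_mask,
    write_regions,
    write_transcripts,
)
from .errors import ConfigError
from .register import (
    LandmarkSet,
    SplineTransform,
    fit_spline_transform,
    read_landmarks,
    registration_error,
    transform_points,
    warp_extent,
    warp_mask,
    write_landmarks,
)
from .simulate import SimConfig, deform_polygon, landmark_grid, make_deformation

logger = logging.getLogger("costack")

_DEFAULT_GATING_TREE = {
    "marker": "PanCK",
    "if_true": "tumour",
    "if_false": {
        "marker": "CD45",
        "if_true": {
            "marker": "CD3",
            "if_true": "t_cell",
            "if_false": {
                "marker": "CD20",
                "if_true": "b_cell",
                "if_false": {
                    "marker": "CD68",
                    "if_true": "macrophage",
                    "if_false": "other_immune",
                },
            },
        },
        "if_false": "stromal",
    },
}

_SP_LABEL_MAP = {
    "tumour": "tumour",
    "t_cell": "t_cell",
    "b_cell": "b_cell",
    "macrophage": "macrophage",
    "stromal": "other",
    "other_immune": "other",
}
_ST_LABEL_MAP = {
    "tumour": "tumour",
    "t_cell": "t_cell",
    "b_cell": "b_cell",
    "macrophage": "macrophage",
    "stromal": "other",
}


def default_pipeline_config(seed: int = 0, n_cells: int = 450) -> dict:
    """Complete declarative pipeline configuration (YAML-serialisable)."""
    simcfg = simulate.default_config(n_cells=n_cells, seed=seed)
    return {
        "seed": seed,
        "sim": simcfg.to_dict(),
        "sim_masks": {"shrink_px": 2.0},
        "registration": {"lam": 0.0, "n_landmark_grid": 5},
        "segmentation": {"min_area_px": 20, "expand_um": 5.0},
        "matching": {"max_dist_um": 15.0},
        "filters": {"min_total_clustering": 20, "dapi_threshold": 0.1},
        "gating": {
            "thresholds": simulate.gating_thresholds(simcfg),
            "tree": _DEFAULT_GATING_TREE,
        },
        "label_maps": {"sp": dict(_SP_LABEL_MAP), "st": dict(_ST_LABEL_MAP)},
        "annotation": {"k": 15, "n_ref_cells": 600, "n_pcs": 10},
        "clustering": {"k": 15, "target_sum": 10000.0, "resolution": 1.0},
        "correlation": {"alpha": 0.05, "n_min": 10},
    }


def _simcfg(cfg: dict) -> SimConfig:
    return SimConfig.from_dict(cfg["sim"])


def _frames(cfg: dict) -> tuple[Frame, Frame, Frame]:
    sim = _simcfg(cfg)
    common = sim.frame
    st = Frame("xenium", common.shape, common.microns_per_pixel)
    sp = Frame("comet", common.shape, common.microns_per_pixel)
    return common, st, sp


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> dict:
    """Generate the synthetic dataset files a real study would provide."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simcfg = _simcfg(cfg)
    common, st_frame, sp_frame = _frames(cfg)
    truth = simulate.simulate_tissue(simcfg)
    counts, proteins = simulate.draw_cell_molecules(truth, simcfg)
    tx_common = simulate.scatter_transcripts(truth, counts, simcfg)

    field_st = make_deformation(simcfg, tag=0)
    field_sp = make_deformation(simcfg, tag=1)
    n_grid = cfg["registration"]["n_landmark_grid"]
    lm_st_train, lm_st_test = landmark_grid(field_st, common, n_grid=n_grid)
    lm_sp_train, lm_sp_test = landmark_grid(field_sp, common, n_grid=n_grid)

    # transcripts observed in the ST frame
    pts = tx_common.data[["x", "y"]].to_numpy()
    moved = field_st.apply(pts)
    df = tx_common.data[["x", "y", "gene"]].copy()
    df["x"], df["y"] = moved[:, 0], moved[:, 1]
    tx_st = TranscriptTable(df, st_frame)
    write_transcripts(tx_st, outdir / "transcripts_st.csv")

    # protein stack observed in the SP frame
    stack_sp = simulate.render_stack(truth, proteins, simcfg, field=field_sp,
                                     frame=sp_frame)
    write_intensity_stack(stack_sp, outdir / "stack_sp.tif")

    # ST DAPI image (nuclei, deformed into the ST frame)
    rng = np.random.default_rng([simcfg.seed, 20])
    dapi = np.zeros(st_frame.shape)
    for cid in truth.cells["cell_id"]:
        nuc = deform_polygon(field_st, truth.nucleus_polygons[cid])
        rr, cc = simulate._polygon_pixels(nuc, st_frame.shape)
        dapi[rr, cc] = proteins.at[cid, simcfg.dapi_channel]
    dapi = np.clip(dapi + rng.normal(0, simcfg.pixel_noise_sd, dapi.shape), 0, None)
    import tifffile

    tifffile.imwrite(outdir / "dapi_st.tif", dapi.astype(np.float32))

    # membrane-based segmentation of the SP data (eroded cells, SP frame)
    shrink = cfg["sim_masks"]["shrink_px"]
    shrunk = {}
    for cid, poly in truth.cell_polygons.items():
        small = poly.buffer(-shrink) if shrink > 0 else poly
        if small.is_empty or small.area < 1.0:
            continue
        if small.geom_type == "MultiPolygon":
            small = max(small.geoms, key=lambda p: p.area)
        shrunk[cid] = small
    mask_sp = simulate.rasterize_cells(shrunk, sp_frame, field=field_sp)
    write_label_mask(mask_sp, outdir / "mask_sp_modframe.tif")

    write_regions(truth.regions, outdir / "regions.geojson")
    truth.cells.to_csv(outdir / "truth_cells.csv", index=False)
    write_landmarks(lm_st_train, outdir / "landmarks_st_train.csv")
    write_landmarks(lm_st_test, outdir / "landmarks_st_test.csv")
    write_landmarks(lm_sp_train, outdir / "landmarks_sp_train.csv")
    write_landmarks(lm_sp_test, outdir / "landmarks_sp_test.csv")
    return {
        "n_cells": int(len(truth.cells)),
        "n_transcripts": int(len(tx_st)),
        "n_cells_mask_sp": int(len(shrunk)),
    }


def stage_register(cfg: dict, outdir: Path) -> dict:
    """Fit one TPS per modality and report held-out residuals."""
    outdir = Path(outdir)
    lam = cfg["registration"]["lam"]
    rows = []
    out = {}
    for mod in ("st", "sp"):
        train = read_landmarks(outdir / f"landmarks_{mod}_train.csv")
        test = read_landmarks(outdir / f"landmarks_{mod}_test.csv")
        T = fit_spline_transform(train, lam=lam)
        T.to_json(outdir / f"transform_{mod}.json")
        err = registration_error(T, test)
        rows.append({"modality": mod, **err})
        out[f"registration_heldout_mean_px_{mod}"] = err["mean_px"]
    pd.DataFrame(rows).to_csv(outdir / "registration_qc.csv", index=False)
    return out


def stage_segment(cfg: dict, outdir: Path) -> dict:
    """Nuclear-expansion segmentation of the ST DAPI; warp masks to common."""
    outdir = Path(outdir)
    import tifffile

    common, st_frame, sp_frame = _frames(cfg)
    seg = cfg["segmentation"]
    dapi = tifffile.imread(outdir / "dapi_st.tif")
    seeds = segment.detect_nuclei(dapi, st_frame, min_area=seg["min_area_px"])
    expand_px = seg["expand_um"] / st_frame.microns_per_pixel
    mask_st_mod = segment.expand_nuclei(seeds, expand_px)
    write_label_mask(mask_st_mod, outdir / "mask_st_modframe.tif")

    T_st = SplineTransform.from_json(outdir / "transform_st.json")
    T_sp = SplineTransform.from_json(outdir / "transform_sp.json")
    mask_st = warp_mask(T_st, mask_st_mod, common)
    mask_sp_mod = read_label_mask(outdir / "mask_sp_modframe.tif", sp_frame)
    mask_sp = warp_mask(T_sp, mask_sp_mod, common)
    write_label_mask(mask_st, outdir / "mask_st_common.tif")
    write_label_mask(mask_sp, outdir / "mask_sp_common.tif")
    return {
        "n_nuclei_detected": int(len(seeds.table)),
        "n_cells_st_common": int(len(mask_st.label_set())),
        "n_cells_sp_common": int(len(mask_sp.label_set())),
    }


def stage_integrate(cfg: dict, outdir: Path) -> dict:
    """Unified per-cell tables for both segmentations in the common frame."""
    outdir = Path(outdir)
    simcfg = _simcfg(cfg)
    common, st_frame, sp_frame = _frames(cfg)
    T_st = SplineTransform.from_json(outdir / "transform_st.json")
    T_sp = SplineTransform.from_json(outdir / "transform_sp.json")

    tx_st = read_transcripts(outdir / "transcripts_st.csv", st_frame,
                             panel=simcfg.genes)
    moved = transform_points(T_st, tx_st.data[["x", "y"]].to_numpy())
    df = tx_st.data[["x", "y", "gene"]].copy()
    df["x"], df["y"] = moved[:, 0], moved[:, 1]
    tx_common = TranscriptTable(df, common)
    write_transcripts(tx_common, outdir / "transcripts_common.csv")

    from shapely.geometry import box

    he_extent = box(0, 0, common.width, common.height)
    roi = integrate.compute_roi_intersection(
        [he_extent, warp_extent(T_st, st_frame), warp_extent(T_sp, sp_frame)]
    )
    regions = read_regions(outdir / "regions.geojson", common)
    stack_sp = read_intensity_stack(outdir / "stack_sp.tif", sp_frame,
                                    dapi_channel=simcfg.dapi_channel)
    T_common_to_sp = T_sp.inverse()

    summary = {}
    for tag in ("st", "sp"):
        mask = read_label_mask(outdir / f"mask_{tag}_common.tif", common)
        counts, unassigned = integrate.assign_transcripts(tx_common, mask)
        counts = counts.reindex(columns=simcfg.genes, fill_value=0).fillna(0).astype(int)
        mask_in_sp = warp_mask(T_common_to_sp, mask, sp_frame)
        intensities = integrate.aggregate_intensities(stack_sp, mask_in_sp)
        cells = integrate.build_cell_table(mask, counts, intensities, regions)
        cells = integrate.restrict_to_roi(cells, roi)
        n_roi = len(cells)
        cells = integrate.filter_cells(cells, {"min_total_transcripts": 1})
        write_cell_table(cells, outdir / f"cells_{tag}_seg.csv")
        summary[f"n_cells_{tag}"] = int(len(cells))
        summary[f"n_zero_transcript_removed_{tag}"] = int(n_roi - len(cells))
        summary[f"unassigned_spots_{tag}"] = int(unassigned)
    return summary


def stage_compare(cfg: dict, outdir: Path) -> dict:
    """Match cells across segmentations and quantify discrepancies."""
    outdir = Path(outdir)
    common, _, _ = _frames(cfg)
    cells_a = pd.read_csv(outdir / "cells_st_seg.csv")
    cells_b = pd.read_csv(outdir / "cells_sp_seg.csv")
    max_dist = cfg["matching"]["max_dist_um"] / common.microns_per_pixel
    match = seg_compare.match_cells(cells_a, cells_b, max_dist)
    match.to_csv(outdir / "match_table.csv", index=False)
    per_pair, summary = seg_compare.discrepancy_metrics(match, cells_a, cells_b)
    per_pair.to_csv(outdir / "discrepancy.csv", index=False)
    summary.to_csv(outdir / "discrepancy_summary.csv", index=False)
    genewise = seg_compare.genewise_seg_correlation(match, cells_a, cells_b)
    genewise.to_csv(outdir / "genewise_seg_correlation.csv", index=False)
    frac_pos = float((per_pair["delta_area"] > 0).mean()) if len(per_pair) else np.nan
    return {
        "n_matched": int(len(match)),
        "matched_delta_area_positive_fraction": frac_pos,
        "genewise_seg_rho_median": float(genewise["rho"].median()),
    }


def stage_correlate(cfg: dict, outdir: Path) -> dict:
    """Transcript-protein correlation, dropout trend, differential corr."""
    outdir = Path(outdir)
    simcfg = _simcfg(cfg)
    ccfg = cfg["correlation"]
    out = {}
    for tag in ("st", "sp"):
        cells = pd.read_csv(outdir / f"cells_{tag}_seg.csv")
        parts = [
            correlate.pair_correlation(cells, simcfg.pairs, region=r)
            for r in ("all", "tumour", "non-tumour")
        ]
        res = pd.concat(parts, ignore_index=True)
        res.to_csv(outdir / f"correlations_{tag}.csv", index=False)
        trend = correlate.dropout_vs_correlation(parts[0])
        diff = correlate.differential_correlation(
            cells, simcfg.pairs, alpha=ccfg["alpha"], n_min=ccfg["n_min"]
        )
        diff.to_csv(outdir / f"diffcorr_{tag}.csv", index=False)
        allr = parts[0].dropna(subset=["rho"])
        out[f"pair_rho_mean_{tag}"] = float(allr["rho"].mean())
        out[f"dropout_trend_stat_{tag}"] = trend["stat"]
        out[f"n_significant_diffcorr_{tag}"] = int(diff["significant"].sum())
    return out


def _reference_embedding(cfg: dict, rng) -> tuple[np.ndarray, np.ndarray, PCA, list]:
    """Fabricated reference atlas: type-profiled NB expression, PCA space."""
    simcfg = _simcfg(cfg)
    n_ref = cfg["annotation"]["n_ref_cells"]
    names = [t.name for t in simcfg.cell_types]
    prev = [t.prevalence for t in simcfg.cell_types]
    types = rng.choice(names, size=n_ref, p=prev)
    spec_of = {t.name: t for t in simcfg.cell_types}
    counts = np.zeros((n_ref, len(simcfg.genes)))
    for j, g in enumerate(simcfg.genes):
        for name in names:
            sel = types == name
            mu = spec_of[name].gene_means.get(g, 0.0)
            theta = spec_of[name].gene_dispersion
            if mu > 0:
                counts[sel, j] = rng.negative_binomial(theta, theta / (theta + mu),
                                                       size=sel.sum())
    totals = counts.sum(axis=1)
    keep = totals > 0
    counts, types = counts[keep], types[keep]
    norm = np.log1p(counts * (cfg["clustering"]["target_sum"] / counts.sum(axis=1))[:, None])
    pca = PCA(n_components=cfg["annotation"]["n_pcs"], svd_solver="full")
    embed = pca.fit_transform(norm)
    return embed, types, pca, simcfg.genes


def stage_annotate(cfg: dict, outdir: Path) -> dict:
    """SP gating + ST label transfer + harmonized Jaccard concordance."""
    outdir = Path(outdir)
    simcfg = _simcfg(cfg)

    # SP arm: DAPI QC filter, rescale to gates, hierarchical gating
    cells_sp = pd.read_csv(outdir / "cells_sp_seg.csv")
    cells_sp = integrate.filter_cells(
        cells_sp, {"min_dapi": cfg["filters"]["dapi_threshold"]}
    )
    thresholds = cfg["gating"]["thresholds"]
    tree = annotate.GateNode.from_dict(cfg["gating"]["tree"])
    used = {m: thresholds[m] for m in tree.markers()}
    rescaled = annotate.rescale_cells(cells_sp, used)
    cells_sp["label_sp"] = annotate.apply_gating(rescaled, tree).to_numpy()
    cells_sp[["cell_id", "label_sp"]].to_csv(outdir / "annotations_sp.csv", index=False)

    # ST arm: kNN transfer in a fabricated reference embedding
    rng = np.random.default_rng([cfg["seed"], 30])
    ref_embed, ref_types, pca, genes = _reference_embedding(cfg, rng)
    cells_st = pd.read_csv(outdir / "cells_st_seg.csv")
    qcounts = cells_st[["gene_" + g for g in genes]].to_numpy(dtype=float)
    qnorm = np.log1p(
        qcounts * (cfg["clustering"]["target_sum"] / qcounts.sum(axis=1))[:, None]
    )
    qembed = pca.transform(qnorm)
    labels, conf = annotate.knn_label_transfer(
        ref_embed, ref_types, qembed, k=cfg["annotation"]["k"]
    )
    cells_st["label_st"] = labels.to_numpy()
    cells_st["label_st_confidence"] = conf.to_numpy()
    cells_st[["cell_id", "label_st", "label_st_confidence"]].to_csv(
        outdir / "annotations_st.csv", index=False
    )

    # concordance on cells matched across the two segmentations
    match = pd.read_csv(outdir / "match_table.csv")
    st_lab = cells_st.set_index("cell_id")["label_st"]
    sp_lab = cells_sp.set_index("cell_id")["label_sp"]
    ok = match["cell_id_a"].isin(st_lab.index) & match["cell_id_b"].isin(sp_lab.index)
    m = match[ok]
    lab_a = annotate.harmonize(
        pd.Series(st_lab.loc[m["cell_id_a"]].to_numpy(), index=m.index),
        cfg["label_maps"]["st"],
    )
    lab_b = annotate.harmonize(
        pd.Series(sp_lab.loc[m["cell_id_b"]].to_numpy(), index=m.index),
        cfg["label_maps"]["sp"],
    )
    conc = annotate.concordance(lab_a, lab_b)
    conc.per_class.to_csv(outdir / "concordance.csv", index=False)
    conc.confusion.to_csv(outdir / "confusion.csv")
    immune = conc.per_class[conc.per_class["class"] != "other"]
    return {
        "n_annotated_pairs": int(len(m)),
        "jaccard_mean": float(immune["jaccard"].mean()),
        "jaccard_max": float(immune["jaccard"].max()),
    }


def stage_cluster(cfg: dict, outdir: Path) -> dict:
    """Filter, normalize, neighbour graph and Louvain on the ST table."""
    outdir = Path(outdir)
    ccfg = cfg["clustering"]
    cells = pd.read_csv(outdir / "cells_st_seg.csv")
    cells = integrate.filter_cells(
        cells, {"min_total_transcripts": cfg["filters"]["min_total_clustering"]}
    )
    gene_cols = [c for c in cells.columns if c.startswith("gene_")]
    counts = cells.set_index("cell_id")[gene_cols]
    norm = cluster.normalize(counts, target_sum=ccfg["target_sum"])
    graph = cluster.knn_graph(norm, k=ccfg["k"], metric="cosine")
    labels = cluster.cluster_cells(graph, seed=cfg["seed"],
                                   resolution=ccfg["resolution"])
    labels.rename_axis("cell_id").reset_index().to_csv(
        outdir / "clusters.csv", index=False
    )
    return {"n_clustered": int(len(labels)), "n_clusters": int(labels.nunique())}


_STAGES = [
    ("simulate", stage_simulate),
    ("register", stage_register),
    ("segment", stage_segment),
    ("integrate", stage_integrate),
    ("compare-seg", stage_compare),
    ("correlate", stage_correlate),
    ("annotate", stage_annotate),
    ("cluster", stage_cluster),
]
STAGE_FUNCS = dict(_STAGES)


def run_all(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Run every stage in order; returns and writes the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = json.loads(json.dumps(cfg))  # deep copy
        cfg["seed"] = int(seed)
        cfg["sim"]["seed"] = int(seed)
    logger.info("run-all seed=%s config=%s", cfg["seed"], config_hash(cfg))
    summary: dict = {"seed": cfg["seed"], "config_hash": config_hash(cfg)}
    for name, fn in _STAGES:
        logger.info("stage %s", name)
        summary.update(fn(cfg, outdir))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
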