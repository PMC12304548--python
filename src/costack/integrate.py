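"""Build the unified per-cell dataset in the common frame.

Transcript spots are assigned to the cell whose mask pixel contains their
coordinate; protein channels are averaged over each cell's pixels; cells
are cropped to the region covered by all modalities (the ROI
intersection), attached to pathology regions by centroid membership, and
passed through the study's exclusion filters (zero-transcript exclusion
always; a minimum-total-count filter before clustering; a DAPI filter
before proteomic gating).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely import contains_xy

from .core_io import (
    CHANNEL_PREFIX,
    GENE_PREFIX,
    IntensityStack,
    LabelMask,
    RegionAnnotation,
    TranscriptTable,
    check_same_frame,
    total_counts,
)
from .errors import ConfigError, ParameterError
from .segment import mask_qc

logger = logging.getLogger("costack")


def compute_roi_intersection(extents):
    """Intersection of modality extents (shapely polygons, common frame).

    Downstream per-cell tables are restricted to cells whose centroid lies
    inside the returned polygon.  An empty intersection is a configuration
    error.
    """
    extents = list(extents)
    if not extents:
        raise ParameterError("no modality extents given")
    roi = extents[0]
    for ext in extents[1:]:
        roi = roi.intersection(ext)
    if roi.is_empty or roi.area <= 0:
        raise ConfigError("modality extents do not overlap (empty ROI intersection)")
    return roi


def assign_transcripts(
    tx: TranscriptTable, mask: LabelMask
) -> tuple[pd.DataFrame, int]:
    """Assign each transcript to the cell label under its coordinate.

    The point ``(x, y)`` maps to pixel ``(floor(y), floor(x))``; label 0 or
    an out-of-frame coordinate means unassigned.  Conservation holds:
    assigned + unassigned = total spots.

    Returns a cell x gene count table (index = cell_id, columns = gene
    names without prefix) and the unassigned spot count.
    """
    check_same_frame(tx.frame, mask.frame, "transcripts and mask")
    df = tx.data
    n_total = len(df)
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    ix = np.floor(x).astype(int)
    iy = np.floor(y).astype(int)
    inside = tx.frame.contains(x, y)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d transcript(s) outside the frame counted unassigned", n_out)
    labels = np.zeros(n_total, dtype=mask.labels.dtype)
    labels[inside] = mask.labels[iy[inside], ix[inside]]
    assigned = labels > 0
    if assigned.any():
        genes = df["gene"].to_numpy()[assigned]
        counts = (
            pd.crosstab(
                pd.Series(labels[assigned], name="cell_id"),
                pd.Series(genes, name="gene"),
            )
            .astype(int)
        )
        counts.columns.name = None
    else:
        counts = pd.DataFrame(dtype=int)
        counts.index.name = "cell_id"
    unassigned = n_total - int(assigned.sum())
    return counts, unassigned


def aggregate_intensities(stack: IntensityStack, mask: LabelMask) -> pd.DataFrame:
    """Mean intensity of every channel over each cell's pixels.

    Cells with no pixels in the mask simply have no row.  Returns a cell x
    channel table (index = cell_id, columns = channel names).
    """
    check_same_frame(stack.frame, mask.frame, "stack and mask")
    labels = mask.labels.ravel()
    present = np.unique(labels)
    present = present[present > 0]
    npix = np.bincount(labels, minlength=labels.max() + 1 if labels.size else 1)
    data = {}
    for i, name in enumerate(stack.channels):
        sums = np.bincount(labels, weights=stack.data[i].ravel(),
                           minlength=len(npix))
        data[name] = sums[present] / npix[present]
    return pd.DataFrame(data, index=pd.Index(present.astype(int), name="cell_id"))


def build_cell_table(
    mask: LabelMask,
    counts: pd.DataFrame | None = None,
    intensities: pd.DataFrame | None = None,
    regions: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """One row per cell: centroid, area, prefixed counts/intensities, region."""
    cells = mask_qc(mask)
    cells = cells.set_index("cell_id")
    if counts is not None:
        pref = counts.add_prefix(GENE_PREFIX)
        cells = cells.join(pref, how="left")
        cells[pref.columns] = cells[pref.columns].fillna(0).astype(int)
    if intensities is not None:
        cells = cells.join(intensities.add_prefix(CHANNEL_PREFIX), how="left")
    cells = cells.reset_index()
    if regions is not None:
        cells = assign_regions(cells, regions)
    return cells


def assign_regions(cells: pd.DataFrame, regions: RegionAnnotation) -> pd.DataFrame:
    """Attach the pathology region containing each cell centroid.

    A centroid inside no polygon gets region ``"none"``.  When polygons of
    different classes overlap, the smallest polygon wins (logged).
    """
    out = cells.copy()
    region = np.full(len(cells), "none", dtype=object)
    claimed = np.zeros(len(cells), dtype=bool)
    polys = sorted(regions.polygons, key=lambda lp: lp[1].area)
    classes = {}
    for label, poly in polys:
        classes.setdefault(label, []).append(poly)
    overlap_logged = False
    for i, (label, poly) in enumerate(polys):
        inside = contains_xy(poly, out["x"].to_numpy(), out["y"].to_numpy())
        newly = inside & ~claimed
        if (inside & claimed & (region != label)).any() and not overlap_logged:
            logger.info("overlapping region polygons of different classes; "
                        "smallest-area polygon wins")
            overlap_logged = True
        region[newly] = label
        claimed |= inside
    out["region"] = region
    return out


def restrict_to_roi(cells: pd.DataFrame, roi) -> pd.DataFrame:
    """Keep cells whose centroid lies inside the ROI intersection."""
    keep = contains_xy(roi, cells["x"].to_numpy(), cells["y"].to_numpy())
    dropped = int((~keep).sum())
    if dropped:
        logger.info("ROI crop removed %d cell(s)", dropped)
    return cells[keep].reset_index(drop=True)


def filter_cells(cells: pd.DataFrame, rule: dict) -> pd.DataFrame:
    """Apply one exclusion rule to a cell table.

    ``{"min_total_transcripts": t}`` keeps cells with total count >= t
    (t = 1 is the zero-transcript exclusion; t = 20 is the pre-clustering
    filter).  ``{"min_dapi": v}`` keeps cells with mean DAPI >= v.
    """
    if len(rule) != 1:
        raise ParameterError(f"filter rule must have exactly one key, got {rule}")
    (key, value), = rule.items()
    if key == "min_total_transcripts":
        keep = total_counts(cells) >= value
    elif key == "min_dapi":
        col = CHANNEL_PREFIX + "DAPI"
        if col not in cells.columns:
            raise ParameterError(f"cell table has no {col} column for min_dapi filter")
        keep = cells[col] >= value
    else:
        raise ParameterError(f"unknown filter rule {key!r}")
    removed = int((~keep).sum())
    logger.info("filter %s=%s removed %d of %d cells", key, value, removed, len(cells))
    return cells[keep].reset_index(drop=True)
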