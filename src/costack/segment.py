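"""Nuclear-expansion cell segmentation and mask QC.

The spatial-transcriptomics arm segments cells by detecting nuclei on the
DAPI channel and growing each nucleus outward by a bounded distance
(nearest-seed assignment, collision-limited), the convention used by
imaging-based in-situ platforms.  Membrane-marker-based masks for the
proteomics arm are produced externally and ingested through
:func:`costack.core_io.read_label_mask`; they are not re-derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core_io import Frame, LabelMask
from .errors import ParameterError

logger = logging.getLogger("costack")


@dataclass
class NucleusSeeds:
    """Detected nuclei: a label mask plus a per-nucleus summary table."""

    mask: LabelMask
    table: pd.DataFrame  # columns: cell_id, x, y, area


def detect_nuclei(
    dapi: np.ndarray,
    frame: Frame,
    min_area: float = 20.0,
    threshold: float | str = "otsu",
    split_min_distance: int = 5,
) -> NucleusSeeds:
    """Detect nuclei on a single-channel DAPI image.

    Global threshold (Otsu by default) -> connected components -> removal of
    components below ``min_area`` -> splitting of touching nuclei by a
    local-maxima watershed on the Euclidean distance transform.

    A constant image yields zero seeds with a warning.
    """
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise ParameterError("DAPI image must be single-channel 2-D")
    if img.max() == img.min():
        logger.warning("DAPI image is constant; no nuclei detected")
        return _empty_seeds(frame)
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    binary = img > thr
    if not binary.any():
        return _empty_seeds(frame)
    # split touching nuclei: markers at local maxima of the distance map
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist, min_distance=split_min_distance, labels=cc_label(binary), exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(binary).astype(np.int32)
    else:
        labels = watershed(-dist, markers, mask=binary).astype(np.int32)
    # drop small components, relabel sequentially in scan order
    out = np.zeros_like(labels)
    next_id = 0
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        next_id += 1
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        out[rr, cc] = next_id
    mask = LabelMask(out, frame)
    return NucleusSeeds(mask, mask_qc(mask).drop(columns=["touches_border"]))


def _empty_seeds(frame: Frame) -> NucleusSeeds:
    mask = LabelMask(np.zeros(frame.shape, dtype=np.int32), frame)
    return NucleusSeeds(mask, mask_qc(mask).drop(columns=["touches_border"]))


def expand_nuclei(seeds: NucleusSeeds | LabelMask, max_dist: float) -> LabelMask:
    """Grow every nucleus outward by up to ``max_dist`` pixels.

    Each background pixel within ``max_dist`` (Euclidean distance to the
    seed *region*, not its centroid) of at least one nucleus is assigned to
    the nearest nucleus; equidistant pixels go to the lowest label id.
    Pixels farther than ``max_dist`` from every seed stay background, and
    seed pixels keep their label, so expansion never creates or merges
    labels and is monotone in ``max_dist``.
    """
    if max_dist < 0:
        raise ParameterError(f"max_dist must be >= 0, got {max_dist}")
    mask = seeds.mask if isinstance(seeds, NucleusSeeds) else seeds
    labels = mask.labels
    out = labels.copy()
    if max_dist == 0 or labels.max() == 0:
        return LabelMask(out, mask.frame)
    h, w = labels.shape
    pad = int(np.ceil(max_dist)) + 1
    best = np.full(labels.shape, np.inf)
    best[labels > 0] = 0.0
    objects = ndi.find_objects(labels)
    # ascending label order + strict-less replacement => lowest-id tie-break
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, h)
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, w)
        win = (slice(r0, r1), slice(c0, c1))
        seed = labels[win] == lab
        d = ndi.distance_transform_edt(~seed)
        take = (d <= max_dist) & (labels[win] == 0) & (d < best[win])
        out[win][take] = lab
        best[win][take] = d[take]
    return LabelMask(out, mask.frame)


def mask_qc(mask: LabelMask) -> pd.DataFrame:
    """Per-cell table: area (px^2), centroid (px, pixel-centre convention),
    and whether the cell touches the image border."""
    labels = mask.labels
    h, w = labels.shape
    rows = []
    for prop in regionprops(labels):
        cy, cx = prop.centroid  # mean of pixel indices (row, col)
        minr, minc, maxr, maxc = prop.bbox
        rows.append(
            {
                "cell_id": int(prop.label),
                "x": float(cx) + 0.5,
                "y": float(cy) + 0.5,
                "area": float(prop.area),
                "touches_border": bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["cell_id", "x", "y", "area", "touches_border"])
    return pd.DataFrame(rows).sort_values("cell_id", ignore_index=True)
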