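"""Domain types and file IO for same-section spatial multi-omics data.

Coordinate convention used throughout the package: 0-based pixel
coordinates, origin at the top-left corner, ``x`` runs along columns and
``y`` along rows.  A point ``(x, y)`` lies in the pixel with indices
``(row=floor(y), col=floor(x))``; image bounds are half-open, so a frame of
shape ``(H, W)`` contains exactly the points with ``0 <= x < W`` and
``0 <= y < H``.  All point data are stored in pixels of the frame they
belong to, with the physical pixel pitch (``microns_per_pixel``) carried as
metadata.  The common frame of a study is the H&E frame; every other
modality is registered onto it.

Per-cell data ("cell tables") are plain :class:`pandas.DataFrame` objects
with one row per cell and a fixed column convention: ``cell_id``, centroid
``x``/``y`` (px), ``area`` (px^2), per-gene transcript counts in columns
prefixed ``gene_``, per-channel mean intensities prefixed ``prot_``, plus
optional ``region`` and per-modality label columns.  Helper functions below
locate the prefixed columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .errors import (
    DimensionError,
    FormatError,
    FrameMismatchError,
    ValidityError,
)

logger = logging.getLogger("costack")

GENE_PREFIX = "gene_"
CHANNEL_PREFIX = "prot_"


# ---------------------------------------------------------------------------
# frames and point data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """A named 2-D raster coordinate system.

    Parameters
    ----------
    name
        Identifier, e.g. ``"he"``, ``"xenium"``, ``"comet"``.
    shape
        ``(height, width)`` in pixels; both components >= 1.
    microns_per_pixel
        Physical pixel pitch, > 0.
    """

    name: str
    shape: tuple[int, int]
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise DimensionError(f"frame shape must be >= 1, got {self.shape}")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        object.__setattr__(self, "shape", (int(h), int(w)))

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def contains(self, x, y) -> np.ndarray:
        """Vectorised half-open bounds test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x < self.width) & (y >= 0) & (y < self.height)

    def compatible(self, other: "Frame") -> bool:
        return self.shape == other.shape and self.name == other.name


def check_same_frame(a: Frame, b: Frame, what: str = "inputs") -> None:
    if not a.compatible(b):
        raise FrameMismatchError(
            f"{what} are in different frames: {a.name}{a.shape} vs {b.name}{b.shape}"
        )


@dataclass
class TranscriptTable:
    """Point-located transcript detections in a stated frame.

    ``data`` holds columns ``x``, ``y`` (px, float), ``gene`` (str) and the
    derived boolean ``in_frame``.  Out-of-frame rows are flagged, never
    silently dropped.
    """

    data: pd.DataFrame
    frame: Frame

    def __post_init__(self) -> None:
        for col in ("x", "y", "gene"):
            if col not in self.data.columns:
                raise FormatError(f"transcript table missing column {col!r}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise FormatError(f"non-finite coordinate at row {bad}")
        self.data = self.data.copy()
        self.data["in_frame"] = self.frame.contains(xy[:, 0], xy[:, 1])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def in_frame(self) -> pd.DataFrame:
        return self.data[self.data["in_frame"]]


def read_transcripts(path, frame: Frame, panel=None) -> TranscriptTable:
    """Read a transcript CSV with header columns ``x,y,gene``.

    Rows outside the frame are flagged via the ``in_frame`` column.  A gene
    not in the declared ``panel`` (when given) is a format error.
    """
    df = pd.read_csv(path, dtype={"gene": str}, float_precision="round_trip")
    for col in ("x", "y", "gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric {col} coordinate at row {int(bad[0])}"
            )
        df[col] = vals.astype(float)
    if panel is not None:
        unknown = sorted(set(df["gene"]) - set(panel))
        if unknown:
            raise FormatError(f"{path}: genes not in declared panel: {unknown}")
    table = TranscriptTable(df[["x", "y", "gene"]], frame)
    n_out = int((~table.data["in_frame"]).sum())
    if n_out:
        logger.warning("%s: %d transcript(s) outside frame %s", path, n_out, frame.name)
    return table


def write_transcripts(table: TranscriptTable, path) -> None:
    table.data[["x", "y", "gene"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

@dataclass
class LabelMask:
    """2-D integer image assigning each pixel to a cell id (0 = background).

    Label ids need not be contiguous; each positive label occupies at least
    one pixel by construction of the readers/operations that produce masks.
    """

    labels: np.ndarray
    frame: Frame

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise DimensionError(f"label mask must be 2-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"label mask must be integer, got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise FormatError("label mask contains negative labels")
        if arr.shape != self.frame.shape:
            raise DimensionError(
                f"mask shape {arr.shape} != frame shape {self.frame.shape}"
            )
        self.labels = arr

    def label_set(self) -> set[int]:
        """Positive labels present in the mask."""
        return set(np.unique(self.labels)) - {0}


def read_label_mask(path, frame: Frame) -> LabelMask:
    """Read a single-plane integer TIFF as a label mask."""
    arr = tifffile.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        raise FormatError(f"{path}: label mask TIFF has float dtype {arr.dtype}")
    if arr.ndim != 2:
        raise DimensionError(f"{path}: expected a single plane, got shape {arr.shape}")
    if arr.shape != frame.shape:
        raise DimensionError(
            f"{path}: TIFF shape {arr.shape} != frame shape {frame.shape}"
        )
    return LabelMask(arr, frame)


def write_label_mask(mask: LabelMask, path) -> None:
    tifffile.imwrite(path, mask.labels)


@dataclass
class IntensityStack:
    """Ordered multi-channel intensity image (one 2-D plane per channel)."""

    channels: list[str]
    data: np.ndarray  # (n_channels, H, W), non-negative float
    frame: Frame
    dapi_channel: str = "DAPI"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3 or arr.shape[0] != len(self.channels):
            raise DimensionError(
                f"stack shape {arr.shape} inconsistent with {len(self.channels)} channels"
            )
        if arr.shape[1:] != self.frame.shape:
            raise DimensionError(
                f"stack planes {arr.shape[1:]} != frame shape {self.frame.shape}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("channel names must be unique")
        if self.dapi_channel not in self.channels:
            raise FormatError(f"no channel designated DAPI ({self.dapi_channel!r})")
        self.data = arr

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


def read_intensity_stack(path, frame: Frame, sidecar=None,
                         dapi_channel: str = "DAPI") -> IntensityStack:
    """Read a channel stack TIFF plus its JSON sidecar of channel names."""
    if sidecar is None:
        sidecar = str(path) + ".json"
    arr = tifffile.imread(path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    channels = list(meta["channels"])
    if arr.ndim == 2:
        arr = arr[None]
    mpp = meta.get("microns_per_pixel")
    if mpp is not None and not np.isclose(mpp, frame.microns_per_pixel):
        raise FrameMismatchError(
            f"{path}: sidecar microns_per_pixel {mpp} != frame {frame.microns_per_pixel}"
        )
    return IntensityStack(channels, arr.astype(float), frame, dapi_channel=dapi_channel)


def write_intensity_stack(stack: IntensityStack, path, sidecar=None) -> None:
    if sidecar is None:
        sidecar = str(path) + ".json"
    tifffile.imwrite(path, stack.data.astype(np.float32))
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "channels": stack.channels,
                "microns_per_pixel": stack.frame.microns_per_pixel,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# region annotations (GeoJSON)
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """Pathology region polygons (class label, closed simple polygon in px)."""

    polygons: list[tuple[str, Polygon]]
    frame: Frame

    def __post_init__(self) -> None:
        for label, poly in self.polygons:
            if not poly.is_valid:
                raise ValidityError(
                    f"region polygon for class {label!r} is not simple/valid"
                )

    def classes(self) -> list[str]:
        return sorted({label for label, _ in self.polygons})


def _feature_class(props: dict) -> str | None:
    """Extract a classification label from QuPath-style GeoJSON properties."""
    if not props:
        return None
    cls = props.get("classification")
    if isinstance(cls, dict):
        return cls.get("name")
    if isinstance(cls, str):
        return cls
    return props.get("class") or props.get("name")


def read_regions(path, frame: Frame, vocabulary=None) -> RegionAnnotation:
    """Read a GeoJSON FeatureCollection of pathology region polygons.

    MultiPolygons are split into their parts (same class); unclassified
    features are kept with class ``"none"`` and a warning; any non-polygonal
    geometry is an error, as is a self-intersecting polygon.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out: list[tuple[str, Polygon]] = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        label = _feature_class(feat.get("properties") or {})
        if label is None:
            logger.warning("%s: feature %d has no classification; using 'none'", path, i)
            label = "none"
        label = str(label).lower()
        if vocabulary is not None:
            label = vocabulary.get(label, label)
        if isinstance(geom, Polygon):
            parts = [geom]
        elif isinstance(geom, MultiPolygon):
            parts = list(geom.geoms)
        else:
            raise FormatError(
                f"{path}: feature {i} has unsupported geometry {geom.geom_type}"
            )
        for part in parts:
            if not part.is_valid:
                raise ValidityError(f"{path}: feature {i} polygon is self-intersecting")
            out.append((label, part))
    return RegionAnnotation(out, frame)


def write_regions(regions: RegionAnnotation, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"classification": {"name": label}},
        }
        for label, poly in regions.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# gene <-> protein pairing
# ---------------------------------------------------------------------------

@dataclass
class PairMap:
    """Gene <-> protein-channel pairing used for cross-modal correlation."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(str(g), str(c)) for g, c in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise FormatError("duplicate gene-channel pairs")

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> list[str]:
        return [g for g, _ in self.pairs]

    def check_against(self, genes, channels) -> None:
        genes, channels = set(genes), set(channels)
        for g, c in self.pairs:
            if g not in genes:
                raise FormatError(f"paired gene {g!r} not in gene panel")
            if c not in channels:
                raise FormatError(f"paired channel {c!r} not in channel panel")


# ---------------------------------------------------------------------------
# cell-table conventions
# ---------------------------------------------------------------------------

def gene_columns(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c.startswith(GENE_PREFIX)]


def channel_columns(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c.startswith(CHANNEL_PREFIX)]


def total_counts(cells: pd.DataFrame) -> pd.Series:
    """Total transcripts per cell over all gene columns."""
    cols = gene_columns(cells)
    if not cols:
        return pd.Series(0, index=cells.index)
    return cells[cols].sum(axis=1)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
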