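"""Synthetic same-section multi-omics tissue with known ground truth.

The generator emulates the observables of a same-section spatial
transcriptomics (ST) + spatial proteomics (SP) experiment on a small tissue
canvas:

* cells of several types laid out as perturbed-Voronoi polygons around
  jittered-grid centres (non-overlapping, nucleus strictly inside cell);
* per-cell transcript counts drawn from gene- and type-specific negative
  binomial (NB) marginals, thinned by gene-specific zero-inflation
  ("dropout"), and scattered uniformly inside the cell polygon together
  with uniform background spots;
* per-cell protein intensities that share a configurable latent *rank*
  correlation with their paired transcripts through a Gaussian copula
  (Pearson parameter ``2 sin(pi * rho_s / 6)`` so the copula's population
  Spearman equals the target), rendered as per-cell-constant values plus
  pixel noise; DAPI is rendered on nuclei and a membrane channel carries a
  boundary highlight;
* two deliberately discrepant segmentations of the same cells
  (over-expanded nuclei vs eroded "membrane" outlines);
* tumour / non-tumour region polygons; and
* a smooth, invertible non-rigid deformation between each modality frame
  and the common frame, with known landmark pairs (including held-out
  pairs) for registration QC.

All randomness flows from ``SimConfig.seed`` through per-operation
:class:`numpy.random.SeedSequence` streams, so every draw is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from scipy.stats import nbinom, norm
from shapely import affinity, contains_xy
from shapely.geometry import Polygon, box
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

from .core_io import (
    Frame,
    IntensityStack,
    LabelMask,
    PairMap,
    RegionAnnotation,
    TranscriptTable,
)
from .errors import CapacityError, ConfigError, ParameterError, ValidityError
from .segment import expand_nuclei

logger = logging.getLogger("costack")

# rng stream tags (second word of the seed sequence)
_TAG_TISSUE = 0
_TAG_MOLECULES = 1
_TAG_DEFORM_BASE = 10


@dataclass
class CellTypeSpec:
    """Generative profile of one cell type."""

    name: str
    prevalence: float
    nuclear_radius: float            # mean nucleus radius, px
    cell_radius: float               # mean cell radius, px
    gene_means: dict[str, float]     # NB mean per gene
    gene_dispersion: float = 2.0     # NB size parameter theta (> 0)
    protein_means: dict[str, float] = field(default_factory=dict)
    protein_log_sd: float = 0.25     # log-normal sd of per-cell protein values


@dataclass
class SimConfig:
    """Full specification of a synthetic same-section dataset.

    ``pair_rho`` maps each paired gene to the target Spearman correlation
    between its latent transcript and protein abundances; ``dropout`` maps
    genes to an extra zero-inflation probability applied after the NB draw.
    """

    frame: Frame
    n_cells: int
    cell_types: list[CellTypeSpec]
    genes: list[str]
    channels: list[str]
    pairs: PairMap
    pair_rho: dict[str, float] = field(default_factory=dict)
    dropout: dict[str, float] = field(default_factory=dict)
    tumour_fraction: float = 0.35
    deform_amplitude: float = 6.0    # max displacement, px
    deform_scale: float = 128.0      # Gaussian bump length scale, px
    background_rate: float = 1e-4    # spurious transcripts per px^2
    pixel_noise_sd: float = 0.05     # additive Gaussian pixel noise
    dapi_channel: str = "DAPI"
    membrane_channel: str | None = "PanCK"
    seed: int = 0

    def __post_init__(self) -> None:
        prev = sum(t.prevalence for t in self.cell_types)
        if not np.isclose(prev, 1.0):
            raise ConfigError(f"cell type prevalences must sum to 1, got {prev}")
        for t in self.cell_types:
            if t.gene_dispersion <= 0:
                raise ConfigError(f"NB dispersion must be > 0 for type {t.name}")
        for g, rho in self.pair_rho.items():
            if abs(rho) > 1:
                raise ConfigError(f"|pair_rho| must be <= 1 (gene {g}: {rho})")
        for g, d in self.dropout.items():
            if not 0 <= d <= 1:
                raise ConfigError(f"dropout must be in [0, 1] (gene {g}: {d})")
        if self.deform_amplitude < 0:
            raise ConfigError("deform_amplitude must be >= 0")
        paired_genes = set(self.pairs.genes())
        self.pairs.check_against(self.genes, self.channels)
        for g in self.pair_rho:
            if g not in paired_genes:
                raise ConfigError(f"pair_rho refers to unpaired gene {g!r}")

    # -- (de)serialisation for YAML configs --------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["frame"] = {
            "name": self.frame.name,
            "shape": list(self.frame.shape),
            "microns_per_pixel": self.frame.microns_per_pixel,
        }
        d["pairs"] = [list(p) for p in self.pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        fr = d["frame"]
        d["frame"] = Frame(fr["name"], tuple(fr["shape"]), fr["microns_per_pixel"])
        d["cell_types"] = [
            t if isinstance(t, CellTypeSpec) else CellTypeSpec(**t)
            for t in d["cell_types"]
        ]
        d["pairs"] = PairMap([tuple(p) for p in d["pairs"]])
        return cls(**d)


@dataclass
class GroundTruth:
    """Known truth behind one synthetic dataset."""

    cells: pd.DataFrame                 # cell_id, cell_type, region, x, y
    cell_polygons: dict[int, Polygon]
    nucleus_polygons: dict[int, Polygon]
    regions: RegionAnnotation
    frame: Frame


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

_DEFAULT_PAIRS = [
    ("CDH1", "ECad"),
    ("KRT15", "CK"),
    ("MS4A1", "CD20"),
    ("CD3E", "CD3"),
    ("CD4", "CD4"),
    ("CD8A", "CD8"),
    ("CD68", "CD68"),
    ("CD14", "CD14"),
    ("FCGR3A", "CD16"),
    ("MKI67", "Ki67"),
]
_DEFAULT_GENES = [g for g, _ in _DEFAULT_PAIRS] + ["PTPRC", "COL1A1"]
_DEFAULT_CHANNELS = [c for _, c in _DEFAULT_PAIRS] + ["CD45", "PanCK", "DAPI"]

# genes markedly expressed per type (others sit at a low baseline)
_TYPE_HIGH_GENES = {
    "tumour": ["CDH1", "KRT15", "MKI67"],
    "t_cell": ["CD3E", "CD4", "CD8A", "PTPRC"],
    "b_cell": ["MS4A1", "PTPRC"],
    "macrophage": ["CD68", "CD14", "FCGR3A", "PTPRC"],
    "stromal": ["COL1A1"],
}
_TYPE_HIGH_CHANNELS = {
    "tumour": ["ECad", "CK", "Ki67", "PanCK"],
    "t_cell": ["CD3", "CD4", "CD8", "CD45"],
    "b_cell": ["CD20", "CD45"],
    "macrophage": ["CD68", "CD14", "CD16", "CD45"],
    "stromal": [],
}
_TYPE_PREVALENCE = {
    "tumour": 0.40,
    "t_cell": 0.20,
    "b_cell": 0.10,
    "macrophage": 0.10,
    "stromal": 0.20,
}


def default_config(
    n_cells: int = 450,
    shape: tuple[int, int] = (512, 512),
    microns_per_pixel: float = 0.5,
    seed: int = 0,
) -> SimConfig:
    """Default study conditions for the synthetic tissue.

    12-gene / 13-channel panel with 10 gene-protein pairs named after the
    markers a lung-cancer immune panel would carry; five cell types; NB
    means 1-20 with dispersion 2; pair Spearman targets 0.3-0.8; a dropout
    gradient 0-0.6 across paired genes; tumour occupying 35% of the canvas;
    deformation amplitude 6 px at length scale 128 px.
    """
    types = []
    for name, prev in _TYPE_PREVALENCE.items():
        gene_means = {
            g: (16.0 if g in _TYPE_HIGH_GENES[name] else 1.2) for g in _DEFAULT_GENES
        }
        protein_means = {
            c: (2.0 if c in _TYPE_HIGH_CHANNELS[name] else 0.15)
            for c in _DEFAULT_CHANNELS
        }
        protein_means["DAPI"] = 3.0
        types.append(
            CellTypeSpec(
                name=name,
                prevalence=prev,
                nuclear_radius=5.0,
                cell_radius=9.0,
                gene_means=gene_means,
                gene_dispersion=2.0,
                protein_means=protein_means,
                protein_log_sd=0.25,
            )
        )
    paired = [g for g, _ in _DEFAULT_PAIRS]
    rho = dict(zip(paired, np.round(np.linspace(0.8, 0.3, len(paired)), 3)))
    drop = dict(zip(paired, np.round(np.linspace(0.0, 0.6, len(paired)), 3)))
    drop.update({"PTPRC": 0.1, "COL1A1": 0.1})
    return SimConfig(
        frame=Frame("he", shape, microns_per_pixel),
        n_cells=n_cells,
        cell_types=types,
        genes=list(_DEFAULT_GENES),
        channels=list(_DEFAULT_CHANNELS),
        pairs=PairMap(list(_DEFAULT_PAIRS)),
        pair_rho={g: float(r) for g, r in rho.items()},
        dropout={g: float(d) for g, d in drop.items()},
        seed=seed,
    )


def gating_thresholds(config: SimConfig) -> dict[str, float]:
    """Raw-intensity positivity thresholds implied by the type profiles.

    Geometric midpoint between the low-baseline and expressing-type medians
    of each channel; used as ground-truth gates in the pipeline config.
    """
    out: dict[str, float] = {}
    for c in config.channels:
        vals = sorted({t.protein_means.get(c, 0.0) for t in config.cell_types})
        if len(vals) == 1:
            out[c] = 0.5 * vals[0]
        else:
            out[c] = float(np.sqrt(max(vals[0], 1e-6) * vals[-1]))
    return out


# ---------------------------------------------------------------------------
# tissue geometry
# ---------------------------------------------------------------------------

def _bounded_voronoi(points: np.ndarray, shape: tuple[int, int]) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the canvas.

    Mirror points across each canvas edge so every region of an original
    point is bounded, then intersect with the canvas rectangle.
    """
    h, w = shape
    mirrored = np.vstack(
        [
            points,
            points * [-1, 1],                 # left edge
            points * [1, -1],                 # top edge
            np.column_stack([2 * w - points[:, 0], points[:, 1]]),
            np.column_stack([points[:, 0], 2 * h - points[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    canvas = box(0.0, 0.0, float(w), float(h))
    polys = []
    for i in range(len(points)):
        verts = vor.vertices[vor.regions[vor.point_region[i]]]
        polys.append(Polygon(verts).intersection(canvas))
    return polys


def simulate_tissue(config: SimConfig) -> GroundTruth:
    """Lay out non-overlapping cells with nuclei and region labels.

    Deterministic given ``config.seed``.  Raises :class:`CapacityError`
    when the requested cells cannot plausibly pack into the canvas
    (n_cells x mean cell area >= 0.7 x canvas area).
    """
    rng = np.random.default_rng([config.seed, _TAG_TISSUE])
    h, w = config.frame.shape
    mean_area = sum(t.prevalence * np.pi * t.cell_radius**2 for t in config.cell_types)
    if config.n_cells * mean_area >= 0.7 * h * w:
        raise CapacityError(
            f"cannot pack {config.n_cells} cells of mean area {mean_area:.0f} px^2 "
            f"into {h}x{w} canvas"
        )
    # jittered-grid centres: collision-free by construction
    nx = int(np.ceil(np.sqrt(config.n_cells * w / h)))
    ny = int(np.ceil(config.n_cells / nx))
    xs = (np.arange(nx) + 0.5) * w / nx
    ys = (np.arange(ny) + 0.5) * h / ny
    gx, gy = np.meshgrid(xs, ys)
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    order = rng.permutation(len(sites))
    sites = sites[order[: config.n_cells]]
    spacing = min(w / nx, h / ny)
    jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=sites.shape)
    centres = np.clip(sites + jitter, [1.0, 1.0], [w - 1.0, h - 1.0])

    polys = _bounded_voronoi(centres, (h, w))

    type_names = [t.name for t in config.cell_types]
    prevalences = [t.prevalence for t in config.cell_types]
    type_of = {t.name: t for t in config.cell_types}
    assigned = rng.choice(type_names, size=config.n_cells, p=prevalences)

    wt = config.tumour_fraction * w
    region_polys: list[tuple[str, Polygon]] = []
    if config.tumour_fraction > 0:
        region_polys.append(("tumour", box(0.0, 0.0, wt, float(h))))
    region_polys.append(("non-tumour", box(wt, 0.0, float(w), float(h))))
    regions = RegionAnnotation(region_polys, config.frame)

    rows, cell_polys, nuc_polys = [], {}, {}
    for i, (poly, tname) in enumerate(zip(polys, assigned), start=1):
        spec = type_of[tname]
        c = poly.centroid
        r_eq = np.sqrt(max(poly.area, 1e-9) / np.pi)
        f_cell = min(0.92, spec.cell_radius / r_eq)
        cell = affinity.scale(poly, xfact=f_cell, yfact=f_cell, origin=(c.x, c.y))
        f_nuc = min(0.9, spec.nuclear_radius / spec.cell_radius)
        nuc = affinity.scale(cell, xfact=f_nuc, yfact=f_nuc, origin=(c.x, c.y))
        region = "tumour" if (config.tumour_fraction > 0 and c.x < wt) else "non-tumour"
        rows.append(
            {
                "cell_id": i,
                "cell_type": tname,
                "region": region,
                "x": float(c.x),
                "y": float(c.y),
            }
        )
        cell_polys[i] = cell
        nuc_polys[i] = nuc
    cells = pd.DataFrame(rows)
    return GroundTruth(cells, cell_polys, nuc_polys, regions, config.frame)


# ---------------------------------------------------------------------------
# molecules: copula-coupled counts and protein values
# ---------------------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter whose population Spearman is rho_s."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def draw_cell_molecules(
    truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell transcript counts and latent protein values.

    For each gene-protein pair the latent (transcript, protein) abundances
    are coupled through a Gaussian copula at the configured rank
    correlation; counts are NB quantiles of the transcript latent, thinned
    by the gene's dropout probability; protein values are log-normal
    quantiles of the protein latent.  Unpaired genes/channels use
    independent latents.  Returns (counts, proteins) DataFrames indexed by
    ``cell_id``.
    """
    rng = np.random.default_rng([config.seed, _TAG_MOLECULES])
    cells = truth.cells
    n = len(cells)
    counts = pd.DataFrame(0, index=cells["cell_id"], columns=config.genes, dtype=int)
    proteins = pd.DataFrame(
        0.0, index=cells["cell_id"], columns=config.channels, dtype=float
    )
    pair_of_gene = dict(config.pairs.pairs)
    type_of = {t.name: t for t in config.cell_types}
    type_arr = cells["cell_type"].to_numpy()

    # transcript latents (paired genes share their z with the protein channel)
    for g in config.genes:
        z_gene = rng.standard_normal(n)
        chan = pair_of_gene.get(g)
        if chan is not None:
            rho_p = spearman_to_pearson(config.pair_rho.get(g, 0.0))
            z_prot = rho_p * z_gene + np.sqrt(max(0.0, 1 - rho_p**2)) * rng.standard_normal(n)
        else:
            z_prot = None
        cnt = np.zeros(n, dtype=int)
        for tname, spec in type_of.items():
            sel = type_arr == tname
            if not sel.any():
                continue
            mu = spec.gene_means.get(g, 0.0)
            if mu <= 0:
                continue
            theta = spec.gene_dispersion
            p = theta / (theta + mu)
            cnt[sel] = nbinom.ppf(norm.cdf(z_gene[sel]), theta, p).astype(int)
        d = config.dropout.get(g, 0.0)
        if d > 0:
            cnt[rng.random(n) < d] = 0
        counts[g] = cnt
        if chan is not None:
            proteins[chan] = _protein_values(z_prot, chan, type_arr, type_of)

    paired_channels = {c for _, c in config.pairs.pairs}
    for c in config.channels:
        if c in paired_channels:
            continue
        proteins[c] = _protein_values(rng.standard_normal(n), c, type_arr, type_of)
    return counts, proteins


def _protein_values(z, channel, type_arr, type_of) -> np.ndarray:
    vals = np.zeros(len(z))
    for tname, spec in type_of.items():
        sel = type_arr == tname
        if not sel.any():
            continue
        mean = spec.protein_means.get(channel, 0.0)
        vals[sel] = mean * np.exp(spec.protein_log_sd * z[sel])
    return vals


def _sample_in_polygon(poly: Polygon, n: int, rng) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if n == 0:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.zeros((n, 2))
    got = 0
    while got < n:
        m = max(32, 2 * (n - got))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = cand[contains_xy(poly, cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def scatter_transcripts(
    truth: GroundTruth, counts: pd.DataFrame, config: SimConfig, rng=None
) -> TranscriptTable:
    """Scatter per-cell counts uniformly inside each cell polygon and add
    uniform background spots (common frame)."""
    if rng is None:
        rng = np.random.default_rng([config.seed, _TAG_MOLECULES, 1])
    h, w = truth.frame.shape
    xs, ys, gs = [], [], []
    for cid, row in counts.iterrows():
        total = int(row.sum())
        if total == 0:
            continue
        pts = _sample_in_polygon(truth.cell_polygons[cid], total, rng)
        genes = np.repeat(row.index.to_numpy(), row.to_numpy())
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        gs.append(genes)
    n_bg = rng.poisson(config.background_rate * h * w)
    if n_bg > 0:
        xs.append(rng.uniform(0, w, n_bg))
        ys.append(rng.uniform(0, h, n_bg))
        gs.append(rng.choice(config.genes, n_bg))
    if xs:
        df = pd.DataFrame(
            {
                "x": np.concatenate(xs),
                "y": np.concatenate(ys),
                "gene": np.concatenate(gs),
            }
        )
    else:
        df = pd.DataFrame({"x": [], "y": [], "gene": []})
    return TranscriptTable(df, truth.frame)


def _polygon_pixels(poly: Polygon, shape: tuple[int, int]):
    ext = np.asarray(poly.exterior.coords)
    rr, cc = draw_polygon(ext[:, 1], ext[:, 0], shape=shape)
    return rr, cc


def render_stack(
    truth: GroundTruth,
    proteins: pd.DataFrame,
    config: SimConfig,
    field: "DeformationField | None" = None,
    frame: Frame | None = None,
    rng=None,
) -> IntensityStack:
    """Render protein channels as per-cell-constant fills plus pixel noise.

    DAPI is rendered on nuclei; the membrane channel additionally gets a
    bright cell-boundary outline.  If ``field`` is given, polygons are
    deformed into the modality frame before rasterisation.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _TAG_MOLECULES, 2])
    frame = frame or truth.frame
    h, w = frame.shape
    data = np.zeros((len(config.channels), h, w))
    chan_idx = {c: i for i, c in enumerate(config.channels)}
    for cid in truth.cells["cell_id"]:
        cell_poly = truth.cell_polygons[cid]
        nuc_poly = truth.nucleus_polygons[cid]
        if field is not None:
            cell_poly = deform_polygon(field, cell_poly)
            nuc_poly = deform_polygon(field, nuc_poly)
        rr, cc = _polygon_pixels(cell_poly, (h, w))
        nrr, ncc = _polygon_pixels(nuc_poly, (h, w))
        for c in config.channels:
            v = proteins.at[cid, c]
            if c == config.dapi_channel:
                data[chan_idx[c]][nrr, ncc] = v
            else:
                data[chan_idx[c]][rr, cc] = v
        if config.membrane_channel and config.membrane_channel in chan_idx:
            ext = np.asarray(cell_poly.exterior.coords)
            prr, pcc = polygon_perimeter(ext[:, 1], ext[:, 0], shape=(h, w))
            data[chan_idx[config.membrane_channel]][prr, pcc] *= 1.5
    if config.pixel_noise_sd > 0:
        data = np.clip(
            data + rng.normal(0, config.pixel_noise_sd, size=data.shape), 0, None
        )
    return IntensityStack(
        list(config.channels), data, frame, dapi_channel=config.dapi_channel
    )


def simulate_molecules(
    truth: GroundTruth, config: SimConfig
) -> tuple[TranscriptTable, IntensityStack]:
    """Full molecular observables in the common frame (no deformation)."""
    counts, proteins = draw_cell_molecules(truth, config)
    tx = scatter_transcripts(truth, counts, config)
    stack = render_stack(truth, proteins, config)
    return tx, stack


# ---------------------------------------------------------------------------
# discrepant segmentations
# ---------------------------------------------------------------------------

def rasterize_cells(
    polygons: dict[int, Polygon],
    frame: Frame,
    field: "DeformationField | None" = None,
) -> LabelMask:
    """Rasterise labelled polygons (optionally deformed) into a label mask."""
    h, w = frame.shape
    out = np.zeros((h, w), dtype=np.int32)
    for cid in sorted(polygons):
        poly = polygons[cid]
        if poly.is_empty:
            continue
        if field is not None:
            poly = deform_polygon(field, poly)
        rr, cc = _polygon_pixels(poly, (h, w))
        out[rr, cc] = cid
    return LabelMask(out, frame)


def make_discrepant_masks(
    truth: GroundTruth, expand_px: float, shrink_px: float
) -> tuple[LabelMask, LabelMask]:
    """Two discrepant segmentations of the same cells.

    Mask A mimics nuclear-expansion segmentation: true nuclei grown outward
    by ``expand_px`` (collision-limited nearest-seed assignment).  Mask B
    mimics membrane-based segmentation: true cell polygons eroded by
    ``shrink_px``.  Both carry the true cell ids; a cell erased entirely by
    the erosion is absent from mask B and logged.
    """
    if expand_px < 0 or shrink_px < 0:
        raise ParameterError("expand_px and shrink_px must be >= 0")
    nuclei = rasterize_cells(truth.nucleus_polygons, truth.frame)
    mask_a = expand_nuclei(nuclei, expand_px)
    shrunk: dict[int, Polygon] = {}
    for cid, poly in truth.cell_polygons.items():
        small = poly.buffer(-shrink_px) if shrink_px > 0 else poly
        if small.is_empty or small.area < 1.0:
            logger.info("cell %d eliminated by %.1f px erosion", cid, shrink_px)
            continue
        if small.geom_type == "MultiPolygon":
            small = max(small.geoms, key=lambda p: p.area)
        shrunk[cid] = small
    mask_b = rasterize_cells(shrunk, truth.frame)
    return mask_a, mask_b


# ---------------------------------------------------------------------------
# non-rigid deformation between modality frames
# ---------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Smooth displacement field: small affine part plus Gaussian bumps.

    Maps common-frame points to modality-frame points via
    ``p -> p + scale_factor * D(p)``.
    """

    rotation: float                  # radians, about the frame centre
    translation: np.ndarray          # (2,)
    centre: np.ndarray               # (2,) frame centre
    bump_centres: np.ndarray         # (k, 2)
    bump_amps: np.ndarray            # (k, 2)
    bump_scale: float
    scale_factor: float = 1.0

    def displacement(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        rel = pts - self.centre
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.column_stack(
            [c * rel[:, 0] - s * rel[:, 1], s * rel[:, 0] + c * rel[:, 1]]
        )
        d = (rot - rel) + self.translation
        if len(self.bump_centres):
            d2 = (
                (pts[:, None, 0] - self.bump_centres[None, :, 0]) ** 2
                + (pts[:, None, 1] - self.bump_centres[None, :, 1]) ** 2
            )
            g = np.exp(-d2 / (2 * self.bump_scale**2))
            d = d + g @ self.bump_amps
        return self.scale_factor * d

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        if pts.size == 0:
            return pts.reshape(0, 2)
        return np.atleast_2d(pts) + self.displacement(pts)


def make_deformation(config: SimConfig, tag: int = 0) -> DeformationField:
    """Draw a smooth deformation with max displacement = amplitude.

    Raises :class:`ValidityError` if the resulting map folds (the identity
    plus displacement has non-positive Jacobian somewhere on the canvas).
    """
    rng = np.random.default_rng([config.seed, _TAG_DEFORM_BASE + tag])
    h, w = config.frame.shape
    k = max(3, int(round(h * w / (2 * config.deform_scale) ** 2)))
    field = DeformationField(
        rotation=rng.normal(0, 0.01),
        translation=rng.normal(0, 1.0, size=2),
        centre=np.array([w / 2, h / 2]),
        bump_centres=rng.uniform([0, 0], [w, h], size=(k, 2)),
        bump_amps=rng.normal(0, 1.0, size=(k, 2)),
        bump_scale=config.deform_scale,
        scale_factor=1.0,
    )
    if config.deform_amplitude == 0:
        field.scale_factor = 0.0
        return field
    # normalise the peak displacement to the requested amplitude; the grid
    # is much finer than the bump scale, so the grid max is the field max
    gx, gy = np.meshgrid(np.linspace(0, w, 128), np.linspace(0, h, 128))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    mags = np.linalg.norm(field.displacement(grid), axis=1)
    field.scale_factor = config.deform_amplitude / (max(mags.max(), 1e-12) * 1.001)
    _check_no_fold(field, config.frame)
    return field


def _check_no_fold(field: DeformationField, frame: Frame, n_grid: int = 32) -> None:
    h, w = frame.shape
    gx, gy = np.meshgrid(np.linspace(0, w, n_grid), np.linspace(0, h, n_grid))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    eps = max(h, w) / (8 * n_grid)
    fx = field.apply(pts + [eps, 0.0]) - field.apply(pts - [eps, 0.0])
    fy = field.apply(pts + [0.0, eps]) - field.apply(pts - [0.0, eps])
    det = (fx[:, 0] * fy[:, 1] - fx[:, 1] * fy[:, 0]) / (4 * eps * eps)
    if det.min() <= 0:
        raise ValidityError(
            f"deformation folds (min Jacobian {det.min():.3g} <= 0); "
            "reduce amplitude or increase scale"
        )


def deform_polygon(field: DeformationField, poly: Polygon, max_seg: float = 4.0) -> Polygon:
    """Apply the field to a polygon (boundary densified first)."""
    from shapely import segmentize

    dense = segmentize(poly, max_seg)
    ext = np.asarray(dense.exterior.coords)
    return Polygon(field.apply(ext))


def landmark_grid(
    field: DeformationField,
    frame: Frame,
    n_grid: int = 5,
    holdout_every: int = 5,
):
    """Landmark pairs (modality -> common) on a regular grid.

    Returns ``(train, held_out)`` :class:`~costack.register.LandmarkSet`
    objects; every ``holdout_every``-th pair is held out for registration
    QC.  At least 8 pairs total are produced.
    """
    from .register import LandmarkSet

    if n_grid * n_grid < 8:
        raise ParameterError("landmark grid must contain >= 8 points")
    h, w = frame.shape
    xs = np.linspace(0.08 * w, 0.92 * w, n_grid)
    ys = np.linspace(0.08 * h, 0.92 * h, n_grid)
    gx, gy = np.meshgrid(xs, ys)
    common = np.column_stack([gx.ravel(), gy.ravel()])
    modality = field.apply(common)
    idx = np.arange(len(common))
    held = idx % holdout_every == holdout_every - 1
    train = LandmarkSet(modality[~held], common[~held])
    test = LandmarkSet(modality[held], common[held])
    return train, test


def deform_modality(
    obj, config: SimConfig, tag: int = 0, n_grid: int = 5
):
    """Deform point data into a modality frame with known landmarks.

    ``obj`` may be an (n, 2) point array or a :class:`TranscriptTable`.
    Returns ``(deformed, train_landmarks, held_out_landmarks, field)``.
    """
    field = make_deformation(config, tag=tag)
    train, test = landmark_grid(field, config.frame, n_grid=n_grid)
    if isinstance(obj, TranscriptTable):
        pts = obj.data[["x", "y"]].to_numpy()
        moved = field.apply(pts)
        df = obj.data.copy()
        df["x"], df["y"] = moved[:, 0], moved[:, 1]
        deformed = TranscriptTable(df[["x", "y", "gene"]], config.frame)
    else:
        deformed = field.apply(np.asarray(obj, dtype=float))
    return deformed, train, test, field
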