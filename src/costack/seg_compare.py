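"""Cross-segmentation comparison of one tissue section.

Two segmentations of the same section (nuclear expansion vs membrane
marker based) disagree systematically in cell size and transcript capture.
This module matches cells between the two masks by nearest centroid
distance (mutual nearest neighbours, one-to-one, distance-capped) and
quantifies per-pair morphological and molecular discrepancies plus
gene-wise inter-segmentation agreement and dropout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .core_io import GENE_PREFIX, gene_columns, total_counts
from .errors import ParameterError

_MATCH_COLS = ["cell_id_a", "cell_id_b", "distance"]


def match_cells(
    cellsA: pd.DataFrame, cellsB: pd.DataFrame, max_dist: float
) -> pd.DataFrame:
    """One-to-one cell matching by nearest centroid distance.

    Mutual-nearest-neighbour pairs with centroid distance <= ``max_dist``,
    accepted in increasing distance order (ties broken by lower id in A).
    Mutual-NN matching is intrinsically one-to-one and symmetric in the two
    tables up to column order.
    """
    if max_dist < 0:
        raise ParameterError("max_dist must be >= 0")
    if len(cellsA) == 0 or len(cellsB) == 0:
        return pd.DataFrame(columns=_MATCH_COLS)
    pa = cellsA[["x", "y"]].to_numpy(dtype=float)
    pb = cellsB[["x", "y"]].to_numpy(dtype=float)
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    d_ab, nn_ab = tree_b.query(pa)   # for each A, nearest B
    _, nn_ba = tree_a.query(pb)      # for each B, nearest A
    ia = np.arange(len(pa))
    mutual = nn_ba[nn_ab] == ia
    ok = mutual & (d_ab <= max_dist)
    out = pd.DataFrame(
        {
            "cell_id_a": cellsA["cell_id"].to_numpy()[ok],
            "cell_id_b": cellsB["cell_id"].to_numpy()[nn_ab[ok]],
            "distance": d_ab[ok],
        }
    )
    return out.sort_values(["distance", "cell_id_a"], ignore_index=True)


def discrepancy_metrics(
    match: pd.DataFrame, cellsA: pd.DataFrame, cellsB: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed per-pair differences (A - B) of area, total count and per-gene
    counts, plus a quantile summary of the headline deltas."""
    a = cellsA.set_index("cell_id")
    b = cellsB.set_index("cell_id")
    genes = sorted(set(gene_columns(cellsA)) & set(gene_columns(cellsB)))
    rows = pd.DataFrame(
        {
            "cell_id_a": match["cell_id_a"].to_numpy(),
            "cell_id_b": match["cell_id_b"].to_numpy(),
        }
    )
    ai = a.loc[rows["cell_id_a"]].reset_index(drop=True)
    bi = b.loc[rows["cell_id_b"]].reset_index(drop=True)
    rows["delta_area"] = ai["area"].to_numpy() - bi["area"].to_numpy()
    rows["delta_total"] = (
        total_counts(ai).to_numpy() - total_counts(bi).to_numpy()
    )
    for g in genes:
        rows["delta_" + g[len(GENE_PREFIX):]] = ai[g].to_numpy() - bi[g].to_numpy()
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    summary = pd.DataFrame(
        {
            "quantile": qs,
            "delta_area": np.quantile(rows["delta_area"], qs) if len(rows) else np.nan,
            "delta_total": np.quantile(rows["delta_total"], qs) if len(rows) else np.nan,
        }
    )
    return rows, summary


def genewise_seg_correlation(
    match: pd.DataFrame, cellsA: pd.DataFrame, cellsB: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Spearman of counts over matched cells, with dropout rates.

    Dropout = fraction of matched cells with zero count, reported for each
    segmentation.  A gene constant in both segmentations has no defined
    correlation and is reported with rho = NaN.
    """
    if len(match) < 3:
        raise ParameterError("need >= 3 matched cells for gene-wise correlation")
    a = cellsA.set_index("cell_id").loc[match["cell_id_a"]]
    b = cellsB.set_index("cell_id").loc[match["cell_id_b"]]
    genes = sorted(set(gene_columns(cellsA)) & set(gene_columns(cellsB)))
    rows = []
    for g in genes:
        va = a[g].to_numpy(dtype=float)
        vb = b[g].to_numpy(dtype=float)
        if np.all(va == va[0]) and np.all(vb == vb[0]):
            rho = np.nan
            note = "constant in both segmentations"
        elif np.all(va == va[0]) or np.all(vb == vb[0]):
            rho = np.nan
            note = "constant in one segmentation"
        else:
            rho = float(spearmanr(va, vb).statistic)
            note = ""
        rows.append(
            {
                "gene": g[len(GENE_PREFIX):],
                "n": len(va),
                "rho": rho,
                "dropout_a": float((va == 0).mean()),
                "dropout_b": float((vb == 0).mean()),
                "note": note,
            }
        )
    return pd.DataFrame(rows)
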