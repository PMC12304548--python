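"""Transcript-protein correlation and region-differential correlation.

For each gene-protein pair, the Spearman rank correlation between the
per-cell transcript count and the per-cell mean immunofluorescence
intensity is computed (average ranks for ties), alongside the gene's
dropout rate — the proportion of cells in which the gene was undetected.
Across pairs, higher dropout is expected to depress the observable
correlation, and that trend is summarised by a rank correlation of dropout
against rho.

Regional differences (tumour vs non-tumour) are tested with Fisher's
Z-test on the atanh-transformed correlations.  Because the correlations
are Spearman, the variance uses the Fieller correction ``1.06 / (n - 3)``
rather than the Pearson ``1 / (n - 3)``.  p-values are two-sided normal;
significance is raw ``p < alpha`` by default (alpha = 0.05), with an
optional Benjamini-Hochberg flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .core_io import CHANNEL_PREFIX, GENE_PREFIX, PairMap
from .errors import ParameterError

RANK_CORR_VAR = 1.06  # Fieller variance factor for Spearman's rho


def _pair_vectors(cells: pd.DataFrame, gene: str, channel: str):
    gcol, ccol = GENE_PREFIX + gene, CHANNEL_PREFIX + channel
    if gcol not in cells.columns:
        raise ParameterError(f"cell table lacks column {gcol!r}")
    if ccol not in cells.columns:
        raise ParameterError(f"cell table lacks column {ccol!r}")
    return cells[gcol].to_numpy(dtype=float), cells[ccol].to_numpy(dtype=float)


def _safe_spearman(x: np.ndarray, y: np.ndarray):
    """(rho, note): rho is NaN with a reason when undefined."""
    if len(x) < 3:
        return np.nan, f"n={len(x)} < 3"
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, "constant vector"
    return float(spearmanr(x, y).statistic), ""


def pair_correlation(
    cells: pd.DataFrame, pairs: PairMap, region: str = "all"
) -> pd.DataFrame:
    """Spearman correlation and dropout per gene-protein pair.

    ``region`` restricts to cells with that region label ("all" uses every
    cell).  Input cells are expected to have already passed the
    zero-transcript exclusion.
    """
    sub = cells if region == "all" else cells[cells["region"] == region]
    rows = []
    for gene, channel in pairs:
        x, y = _pair_vectors(sub, gene, channel)
        rho, note = _safe_spearman(x, y)
        rows.append(
            {
                "gene": gene,
                "channel": channel,
                "region": region,
                "n": len(x),
                "rho": rho,
                "dropout": float((x == 0).mean()) if len(x) else np.nan,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def dropout_vs_correlation(results: pd.DataFrame) -> dict:
    """Rank-correlation trend of dropout against rho across pairs.

    A negative statistic means pairs with higher dropout correlate less.
    Undefined (with a reason) for < 3 usable pairs or constant dropout.
    """
    usable = results.dropna(subset=["rho", "dropout"])
    if len(usable) < 3:
        return {"stat": np.nan, "n_pairs": int(len(usable)),
                "note": "fewer than 3 pairs with defined rho"}
    d = usable["dropout"].to_numpy()
    r = usable["rho"].to_numpy()
    if np.all(d == d[0]):
        return {"stat": np.nan, "n_pairs": int(len(usable)),
                "note": "constant dropout across pairs"}
    stat = float(spearmanr(d, r).statistic)
    return {"stat": stat, "n_pairs": int(len(usable)), "note": ""}


def fisher_z_stat(
    rho1: float, n1: int, rho2: float, n2: int, rank_corr: bool = True
) -> tuple[float, float]:
    """Fisher Z statistic and two-sided p for a difference of correlations.

    ``z = (atanh(rho1) - atanh(rho2)) / sqrt(c/(n1-3) + c/(n2-3))`` with
    ``c = 1.06`` for rank correlations (Fieller) and 1 otherwise.
    """
    if min(n1, n2) <= 3:
        raise ParameterError("Fisher Z requires n > 3 in both groups")
    c = RANK_CORR_VAR if rank_corr else 1.0
    se = np.sqrt(c / (n1 - 3) + c / (n2 - 3))
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / se
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)


def differential_correlation(
    cells: pd.DataFrame,
    pairs: PairMap,
    alpha: float = 0.05,
    n_min: int = 10,
    regions: tuple[str, str] = ("tumour", "non-tumour"),
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Tumour vs non-tumour differential correlation per pair.

    Pairs where either region has fewer than ``n_min`` cells, or an
    undefined correlation, are reported with a reason instead of a test.
    """
    r1, r2 = regions
    sub1 = cells[cells["region"] == r1]
    sub2 = cells[cells["region"] == r2]
    rows = []
    for gene, channel in pairs:
        x1, y1 = _pair_vectors(sub1, gene, channel)
        x2, y2 = _pair_vectors(sub2, gene, channel)
        n1, n2 = len(x1), len(x2)
        if min(n1, n2) < n_min:
            rows.append(_dc_row(gene, channel, np.nan, n1, np.nan, n2,
                                note=f"region with n < {n_min}"))
            continue
        rho1, note1 = _safe_spearman(x1, y1)
        rho2, note2 = _safe_spearman(x2, y2)
        if note1 or note2:
            rows.append(_dc_row(gene, channel, rho1, n1, rho2, n2,
                                note=note1 or note2))
            continue
        z, p = fisher_z_stat(rho1, n1, rho2, n2)
        rows.append(_dc_row(gene, channel, rho1, n1, rho2, n2, z=z, p=p))
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    if bh_correct and tested.any():
        from statsmodels.stats.multitest import multipletests

        rej, p_adj, _, _ = multipletests(
            out.loc[tested, "p_value"], alpha=alpha, method="fdr_bh"
        )
        out["p_adj"] = np.nan
        out.loc[tested, "p_adj"] = p_adj
        out["significant"] = False
        out.loc[tested, "significant"] = rej
    else:
        out["significant"] = tested & (out["p_value"] < alpha)
    return out


def _dc_row(gene, channel, rho1, n1, rho2, n2, z=np.nan, p=np.nan, note=""):
    return {
        "gene": gene,
        "channel": channel,
        "rho_tumour": rho1,
        "n_tumour": n1,
        "rho_non": rho2,
        "n_non": n2,
        "z_stat": z,
        "p_value": p,
        "note": note,
    }
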