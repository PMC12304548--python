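"""Cell-type annotation per modality and cross-modality concordance.

The proteomics arm is annotated by threshold-rescaled hierarchical gating:
each marker's raw per-cell mean intensity is rescaled so that its gate
maps to 0.5 (values above 0.5 are marker-positive), and a fixed
marker/threshold decision tree assigns a label root-to-leaf (broad markers
first — e.g. tumour via PanCK, immune via CD45 — refined into
subpopulations).  The transcriptomics arm is annotated by k-nearest-
neighbour label transfer in a user-supplied reference embedding.  Fine
labels from either arm are harmonized onto a shared coarse vocabulary and
compared per class with the Jaccard index |A ∩ B| / |A ∪ B| over matched
cells, alongside a full confusion table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core_io import CHANNEL_PREFIX
from .errors import AlignmentError, ConfigError, ParameterError

logger = logging.getLogger("costack")


# ---------------------------------------------------------------------------
# marker rescaling
# ---------------------------------------------------------------------------

def rescale_marker(values, threshold: float, upper_q: float = 0.99) -> np.ndarray:
    """Rescale raw intensities to [0, 1] with the gate at 0.5.

    Piecewise-linear: [min, t] -> [0, 0.5]; [t, q99] -> [0.5, 1]; clipped
    at 1 above the ``upper_q`` quantile.  Positivity is preserved exactly:
    rescaled > 0.5 iff raw > t (when the gate lies strictly inside the
    observed range; degenerate gates are allowed with a warning).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ParameterError("marker values must be finite")
    lo = v.min()
    hi = np.quantile(v, upper_q)
    t = float(threshold)
    if not lo < t < v.max():
        logger.warning(
            "gate %.4g outside observed range [%.4g, %.4g]; all cells on one side",
            t, lo, v.max(),
        )
    out = np.empty_like(v)
    below = v <= t
    if t > lo:
        out[below] = 0.5 * (v[below] - lo) / (t - lo)
    else:
        out[below] = 0.5
    if hi > t:
        out[~below] = 0.5 + 0.5 * (v[~below] - t) / (hi - t)
    else:
        out[~below] = 1.0
    return np.clip(out, 0.0, 1.0)


def rescale_cells(
    cells: pd.DataFrame, thresholds: dict[str, float], upper_q: float = 0.99
) -> pd.DataFrame:
    """Rescaled marker matrix (columns = marker names) for gating."""
    out = {}
    for marker, t in thresholds.items():
        col = CHANNEL_PREFIX + marker
        if col not in cells.columns:
            raise ConfigError(f"marker {marker!r} not present in cell table")
        out[marker] = rescale_marker(cells[col].to_numpy(), t, upper_q=upper_q)
    return pd.DataFrame(out, index=cells.index)


# ---------------------------------------------------------------------------
# hierarchical gating
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    """One decision node: marker relation threshold, true/false children.

    Children are either another :class:`GateNode` or a leaf label string.
    """

    marker: str
    relation: str = "ge"          # "ge" (>=) or "lt" (<)
    threshold: float = 0.5
    if_true: "GateNode | str" = "positive"
    if_false: "GateNode | str" = "negative"

    def __post_init__(self) -> None:
        if self.relation not in ("ge", "lt"):
            raise ConfigError(f"gate relation must be 'ge' or 'lt', got {self.relation!r}")

    @classmethod
    def from_dict(cls, d: "dict | str") -> "GateNode | str":
        if isinstance(d, str):
            return d
        return cls(
            marker=d["marker"],
            relation=d.get("relation", "ge"),
            threshold=float(d.get("threshold", 0.5)),
            if_true=cls.from_dict(d.get("if_true", "positive")),
            if_false=cls.from_dict(d.get("if_false", "negative")),
        )

    def to_dict(self) -> dict:
        def enc(c):
            return c if isinstance(c, str) else c.to_dict()

        return {
            "marker": self.marker,
            "relation": self.relation,
            "threshold": self.threshold,
            "if_true": enc(self.if_true),
            "if_false": enc(self.if_false),
        }

    def markers(self) -> set[str]:
        out = {self.marker}
        for child in (self.if_true, self.if_false):
            if isinstance(child, GateNode):
                out |= child.markers()
        return out


def apply_gating(rescaled: pd.DataFrame, tree: GateNode) -> pd.Series:
    """Deterministic root-to-leaf label per cell from rescaled markers."""
    missing = tree.markers() - set(rescaled.columns)
    if missing:
        raise ConfigError(f"gating tree references absent markers: {sorted(missing)}")
    labels = pd.Series("", index=rescaled.index, dtype=object)

    def descend(node, idx):
        if isinstance(node, str):
            labels.loc[idx] = node
            return
        vals = rescaled.loc[idx, node.marker]
        pos = vals >= node.threshold if node.relation == "ge" else vals < node.threshold
        descend(node.if_true, idx[pos])
        descend(node.if_false, idx[~pos])

    descend(tree, rescaled.index)
    return labels


# ---------------------------------------------------------------------------
# kNN label transfer
# ---------------------------------------------------------------------------

def knn_label_transfer(
    ref_embed: np.ndarray,
    ref_labels,
    query_embed: np.ndarray,
    k: int = 15,
) -> tuple[pd.Series, pd.Series]:
    """Majority-vote label transfer in a shared embedding.

    Each query takes the majority label of its ``k`` Euclidean nearest
    reference points; confidence is the vote fraction (in [1/k, 1]).  Vote
    ties break by smaller mean neighbour distance, then lexicographically.
    """
    ref_embed = np.asarray(ref_embed, dtype=float)
    query_embed = np.atleast_2d(np.asarray(query_embed, dtype=float))
    ref_labels = np.asarray(ref_labels, dtype=object)
    if len(ref_embed) == 0:
        raise ParameterError("reference embedding is empty")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if ref_embed.shape[1] != query_embed.shape[1]:
        raise ParameterError("reference and query embeddings differ in dimension")
    k = min(k, len(ref_embed))
    nn = NearestNeighbors(n_neighbors=k).fit(ref_embed)
    dist, idx = nn.kneighbors(query_embed)
    labels, conf = [], []
    for di, ii in zip(dist, idx):
        lab = ref_labels[ii]
        uniq, counts = np.unique(lab, return_counts=True)
        best = counts.max()
        cand = uniq[counts == best]
        if len(cand) > 1:
            means = [di[lab == c].mean() for c in cand]
            order = np.lexsort((cand.astype(str), means))
            winner = cand[order[0]]
        else:
            winner = cand[0]
        labels.append(winner)
        conf.append(best / k)
    return pd.Series(labels, dtype=object), pd.Series(conf, dtype=float)


# ---------------------------------------------------------------------------
# harmonization and concordance
# ---------------------------------------------------------------------------

def harmonize(labels: pd.Series, mapping: dict[str, str]) -> pd.Series:
    """Map fine labels to the coarse shared vocabulary (total mapping)."""
    labels = pd.Series(labels, dtype=object)
    unmapped = sorted(set(labels.unique()) - set(mapping))
    if unmapped:
        raise ConfigError(f"label map does not cover: {unmapped}")
    return labels.map(mapping)


@dataclass
class ConcordanceResult:
    """Per-class Jaccard indices and the full confusion table."""

    per_class: pd.DataFrame    # class, intersection, union, jaccard
    confusion: pd.DataFrame    # rows = labels A, cols = labels B


def concordance(
    labelsA: pd.Series, labelsB: pd.Series, classes=None
) -> ConcordanceResult:
    """Per-class Jaccard agreement between two labelings of the same cells.

    Both series must be indexed by the same matched cell ids.  For class
    ``c``, ``J = |A_c ∩ B_c| / |A_c ∪ B_c|``; a class absent from both
    sides has an empty union and an undefined (NaN) Jaccard.
    """
    labelsA = pd.Series(labelsA, dtype=object)
    labelsB = pd.Series(labelsB, dtype=object)
    if not labelsA.index.sort_values().equals(labelsB.index.sort_values()):
        raise AlignmentError("label vectors are not indexed by the same cell ids")
    labelsB = labelsB.reindex(labelsA.index)
    if classes is None:
        classes = sorted(set(labelsA.unique()) | set(labelsB.unique()))
    rows = []
    for c in classes:
        a_set = set(labelsA.index[labelsA == c])
        b_set = set(labelsB.index[labelsB == c])
        union = a_set | b_set
        inter = a_set & b_set
        rows.append(
            {
                "class": c,
                "intersection": len(inter),
                "union": len(union),
                "jaccard": len(inter) / len(union) if union else np.nan,
            }
        )
    confusion = pd.crosstab(labelsA, labelsB, dropna=False)
    confusion.index.name = "labels_a"
    confusion.columns.name = "labels_b"
    return ConcordanceResult(pd.DataFrame(rows), confusion)
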