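"""Per-cell reliability scores, the permutation null, and classification.

A cell's reliability score asks whether its mid-range neighborhood survived
the 2D embedding. Let m = round(x/100 * n) (half-up, clamped to [2, n-1])
with x the similarity percent. For cell i:

* A = the m nearest cells in the PRE-embedding space, ordered closest to
  farthest;
* B = the m nearest cells in the 2D-EMBEDDING space, same ordering;
* v_pre = cell i's 2D-embedding distances to the cells of A, in A's order;
* v_emb = cell i's 2D-embedding distances to the cells of B, in B's order
  (non-decreasing by construction).

The score is the Pearson correlation of v_pre and v_emb. Both vectors are
measured in the 2D space — only the neighbor ORDER differs between spaces —
so the actual embedded distances matter, not just ranks. If the true
neighbors stayed nearby and in order, the score approaches 1.

The null distribution comes from redoing the whole procedure on a gene-wise
permuted copy of the data, where any neighbor agreement is chance. Cells at
or below the 5th percentile of the null scores are "dubious", at or above
the 95th "trustworthy"; the rest are intermediate. A cell whose distance
vector is constant (perfectly equidistant neighbors) has no defined
correlation and is labeled "undefined" and excluded from counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import RunConfig, ValidationError
from .embedders import Embedding2D, HyperparamSetting, embed
from .io import GeneCellMatrix
from .preembedding import PreEmbedding, build_pre_embedding, permute_genes

LABEL_DUBIOUS = "dubious"
LABEL_TRUSTWORTHY = "trustworthy"
LABEL_INTERMEDIATE = "intermediate"
LABEL_UNDEFINED = "undefined"


class DegenerateNullError(ValueError):
    """All null reliability scores are undefined; cutoffs cannot be formed."""


def neighborhood_size(similarity_percent: float, n_cells: int) -> int:
    """m = round(x/100 * n) with half-up rounding, clamped to [2, n-1]."""
    if not 0 < similarity_percent <= 100:
        raise ValidationError("similarity_percent must be in (0, 100]")
    m = int(np.floor(similarity_percent / 100.0 * n_cells + 0.5))
    return int(np.clip(m, 2, n_cells - 1))


def _coords(obj) -> np.ndarray:
    if isinstance(obj, (PreEmbedding, Embedding2D)):
        return obj.coords
    return np.asarray(obj, dtype=float)


def ordered_neighbors(coords, cell: int, m: int) -> np.ndarray:
    """Indices of the m nearest cells to ``cell`` (self excluded), closest
    first; Euclidean distance, ties broken by ascending cell index."""
    X = _coords(coords)
    n = X.shape[0]
    if not 1 <= m <= n - 1:
        raise ValidationError(f"m must be in [1, {n - 1}], got {m}")
    d = np.linalg.norm(X - X[cell], axis=1)
    d[cell] = np.inf  # exclude self
    order = np.argsort(d, kind="stable")  # stable sort = index tie-break
    return order[:m]


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Textbook Pearson r; NaN when either vector has zero variance."""
    if np.all(u == u[0]) or np.all(v == v[0]):
        return float("nan")
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt((du @ du) * (dv @ dv))
    if denom == 0:
        return float("nan")
    return float(np.clip((du @ dv) / denom, -1.0, 1.0))


def reliability_score(pre, emb, cell: int, m: int) -> float:
    """Reliability score of one cell; NaN when undefined."""
    pre_c = _coords(pre)
    emb_c = _coords(emb)
    if pre_c.shape[0] != emb_c.shape[0]:
        raise ValidationError("pre-embedding and embedding are misaligned")
    if m < 2:
        raise ValidationError("m must be >= 2")
    A = ordered_neighbors(pre_c, cell, m)
    B = ordered_neighbors(emb_c, cell, m)
    d_emb = np.linalg.norm(emb_c - emb_c[cell], axis=1)
    return _pearson(d_emb[A], d_emb[B])


def reliability_scores_all(pre, emb, similarity_percent: float = 50.0) -> np.ndarray:
    """Reliability scores of all n cells with m = round(x/100 * n).

    Order matches the cell order of the inputs; undefined scores are NaN.
    """
    pre_c = _coords(pre)
    emb_c = _coords(emb)
    n = pre_c.shape[0]
    if emb_c.shape[0] != n:
        raise ValidationError("pre-embedding and embedding are misaligned")
    if n < 4:
        raise ValidationError("need at least 4 cells")
    m = neighborhood_size(similarity_percent, n)

    D_pre = cdist(pre_c, pre_c)
    D_emb = cdist(emb_c, emb_c)
    idx = np.arange(n)
    D_pre_sort = D_pre.copy()
    D_emb_sort = D_emb.copy()
    D_pre_sort[idx, idx] = np.inf
    D_emb_sort[idx, idx] = np.inf

    scores = np.empty(n)
    for i in range(n):
        A = np.argsort(D_pre_sort[i], kind="stable")[:m]
        B = np.argsort(D_emb_sort[i], kind="stable")[:m]
        scores[i] = _pearson(D_emb[i, A], D_emb[i, B])
    return scores


def null_reliability_scores(
    matrix: GeneCellMatrix, cfg: RunConfig, setting: HyperparamSetting
) -> np.ndarray:
    """Null scores: permute genes, rebuild the pre-embedding, re-embed with
    the same setting and seed, and score the permuted dataset."""
    permuted = permute_genes(matrix, cfg.permute_seed)
    pre_null = build_pre_embedding(permuted, cfg)
    emb_null = embed(pre_null, setting, cfg.embed_seed)
    return reliability_scores_all(pre_null, emb_null, cfg.similarity_percent)


@dataclass
class ReliabilityResult:
    """Scores, null scores, percentile cutoffs and per-cell labels."""

    scores: np.ndarray
    null_scores: np.ndarray
    dubious_cutoff: float
    trustworthy_cutoff: float
    labels: np.ndarray  # of strings
    neighborhood_size: int
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_ids:
            self.cell_ids = [f"cell{i + 1}" for i in range(len(self.scores))]

    @property
    def n_cells(self) -> int:
        return len(self.scores)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    @property
    def n_dubious(self) -> int:
        return self.count(LABEL_DUBIOUS)

    @property
    def n_trustworthy(self) -> int:
        return self.count(LABEL_TRUSTWORTHY)

    @property
    def n_undefined(self) -> int:
        return self.count(LABEL_UNDEFINED)

    @property
    def pct_dubious(self) -> float:
        return 100.0 * self.n_dubious / self.n_cells

    @property
    def pct_trustworthy(self) -> float:
        return 100.0 * self.n_trustworthy / self.n_cells

    def to_frame(self) -> pd.DataFrame:
        score_col = [
            "" if np.isnan(s) else repr(float(s)) for s in self.scores
        ]
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "reliability_score": score_col,
                "label": self.labels,
            }
        )

    def summary(self) -> str:
        return (
            f"{self.n_cells} cells: {self.n_dubious} dubious "
            f"({self.pct_dubious:.2f}%), {self.n_trustworthy} trustworthy "
            f"({self.pct_trustworthy:.2f}%), "
            f"{self.count(LABEL_INTERMEDIATE)} intermediate, "
            f"{self.n_undefined} undefined; cutoffs "
            f"[{self.dubious_cutoff:.4f}, {self.trustworthy_cutoff:.4f}], "
            f"m = {self.neighborhood_size}"
        )


def classify(
    scores: np.ndarray,
    null_scores: np.ndarray,
    dubious_percentile: float = 5.0,
    trustworthy_percentile: float = 95.0,
    cell_ids: list[str] | None = None,
    neighborhood_size_used: int = 0,
) -> ReliabilityResult:
    """Label each cell against percentile cutoffs of the null scores.

    Cutoffs are empirical percentiles with linear interpolation between
    order statistics (h = 1 + p(n-1)). A cell is dubious iff its score is
    <= the dubious cutoff, trustworthy iff >= the trustworthy cutoff,
    undefined iff its score is NaN, otherwise intermediate. Undefined null
    scores are dropped before taking percentiles.
    """
    scores = np.asarray(scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    if not 0 < dubious_percentile < trustworthy_percentile < 100:
        raise ValidationError(
            "need 0 < dubious_percentile < trustworthy_percentile < 100"
        )
    null_valid = null_scores[~np.isnan(null_scores)]
    if null_valid.size == 0:
        raise DegenerateNullError("all null reliability scores are undefined")
    dubious_cutoff, trustworthy_cutoff = np.percentile(
        null_valid, [dubious_percentile, trustworthy_percentile]
    )
    labels = np.full(scores.shape, LABEL_INTERMEDIATE, dtype=object)
    labels[np.isnan(scores)] = LABEL_UNDEFINED
    with np.errstate(invalid="ignore"):
        labels[scores <= dubious_cutoff] = LABEL_DUBIOUS
        labels[scores >= trustworthy_cutoff] = LABEL_TRUSTWORTHY
    return ReliabilityResult(
        scores=scores,
        null_scores=null_scores,
        dubious_cutoff=float(dubious_cutoff),
        trustworthy_cutoff=float(trustworthy_cutoff),
        labels=labels.astype(str),
        neighborhood_size=neighborhood_size_used,
        cell_ids=list(cell_ids) if cell_ids else [],
    )


def score_embedding(
    matrix: GeneCellMatrix,
    cfg: RunConfig,
    setting: HyperparamSetting,
    pre: PreEmbedding | None = None,
    pre_null: PreEmbedding | None = None,
) -> ReliabilityResult:
    """Full single-setting pipeline: embed original and permuted data, score
    both, classify against the null.

    ``pre`` and ``pre_null`` may be passed to reuse pre-embeddings across
    settings (they do not depend on the embedder hyperparameters).
    """
    if pre is None:
        pre = build_pre_embedding(matrix, cfg)
    if pre_null is None:
        permuted = permute_genes(matrix, cfg.permute_seed)
        pre_null = build_pre_embedding(permuted, cfg)
    emb = embed(pre, setting, cfg.embed_seed)
    emb_null = embed(pre_null, setting, cfg.embed_seed)
    scores = reliability_scores_all(pre, emb, cfg.similarity_percent)
    null_scores = reliability_scores_all(pre_null, emb_null, cfg.similarity_percent)
    return classify(
        scores,
        null_scores,
        cfg.dubious_percentile,
        cfg.trustworthy_percentile,
        cell_ids=list(matrix.cell_ids),
        neighborhood_size_used=neighborhood_size(cfg.similarity_percent, matrix.n_cells),
    )
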