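"""Hyperparameter optimization by minimizing the number of dubious embeddings.

A grid of candidate settings is evaluated with the full pipeline (embed the
original data; embed the gene-permuted data; score both; classify), and the
setting with the fewest dubious cell embeddings wins. For UMAP the two
hyperparameters can be swept jointly (Cartesian product) or marginally (one
varies while the other is anchored). An alternative selector picks the elbow
("knee") of the dubious-count curve via the kneedle procedure instead of the
global minimum.

Ties at the minimum go to the smallest hyperparameter value (first in
ascending grid order); all minimizers are reported. This avoids any bias
toward large neighborhood sizes, where dubious counts often plateau.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .config import RunConfig, ValidationError
from .embedders import HyperparamSetting
from .io import GeneCellMatrix
from .preembedding import build_pre_embedding, permute_genes
from .reliability import ReliabilityResult, score_embedding

logger = logging.getLogger(__name__)

#: Default candidate perplexity values: 20 to 380 by 30, then 410, then 450
#: to 750 by 50, then 800.
TSNE_PERPLEXITIES = tuple(range(20, 381, 30)) + (410,) + tuple(range(450, 751, 50)) + (800,)

#: Default candidate n_neighbors values: 5..30, then 35, 40, 45, 50.
UMAP_N_NEIGHBORS = tuple(range(5, 31)) + (35, 40, 45, 50)

#: Default candidate min_dist values.
UMAP_MIN_DISTS = (0.0125, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

# umap-learn library defaults, used as marginal-mode anchors when the user
# supplies no original setting.
DEFAULT_ANCHOR_N_NEIGHBORS = 15
DEFAULT_ANCHOR_MIN_DIST = 0.1


@dataclass
class HyperparamGrid:
    """Candidate hyperparameter values for one embedding method.

    ``mode`` applies to UMAP: ``"joint"`` sweeps the Cartesian product of
    ``n_neighbors_values`` and ``min_dist_values``; ``"marginal"`` varies one
    while the other sits at its anchor (first all n_neighbors values at the
    anchored min_dist, then all min_dist values at the anchored n_neighbors);
    ``"fixed"`` evaluates a single setting (each list of length 1). t-SNE
    grids are one-dimensional and ignore ``mode``.
    """

    method: str
    perplexity_values: tuple = ()
    n_neighbors_values: tuple = ()
    min_dist_values: tuple = ()
    mode: str = "joint"
    anchor_n_neighbors: int | None = None
    anchor_min_dist: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("tsne", "umap"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.mode not in ("fixed", "marginal", "joint"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        def check(name, values):
            values = tuple(values)
            if not values:
                raise ValidationError(f"{name} is empty")
            if any(b <= a for a, b in zip(values, values[1:])):
                raise ValidationError(f"{name} must be strictly increasing")
            return values
        if self.method == "tsne":
            self.perplexity_values = check("perplexity_values", self.perplexity_values)
        else:
            self.n_neighbors_values = check("n_neighbors_values", self.n_neighbors_values)
            self.min_dist_values = check("min_dist_values", self.min_dist_values)
            if self.mode == "fixed" and (
                len(self.n_neighbors_values) != 1 or len(self.min_dist_values) != 1
            ):
                raise ValidationError("fixed mode takes exactly one value per list")


def default_grid(method: str, n_cells: int) -> HyperparamGrid:
    """The default candidate grid, filtered to values feasible for n cells.

    t-SNE perplexities must satisfy perplexity < (n-1)/3; UMAP n_neighbors
    must be < n.
    """
    if n_cells < 4:
        raise ValidationError("need at least 4 cells")
    if method == "tsne":
        feasible = tuple(p for p in TSNE_PERPLEXITIES if p < (n_cells - 1) / 3)
        if not feasible:
            raise ValidationError(
                f"no default perplexity is feasible for n = {n_cells}"
            )
        return HyperparamGrid(method="tsne", perplexity_values=feasible)
    if method == "umap":
        feasible = tuple(k for k in UMAP_N_NEIGHBORS if k < n_cells)
        if not feasible:
            raise ValidationError(
                f"no default n_neighbors is feasible for n = {n_cells}"
            )
        return HyperparamGrid(
            method="umap",
            n_neighbors_values=feasible,
            min_dist_values=UMAP_MIN_DISTS,
        )
    raise ValidationError(f"unknown method {method!r}")


def enumerate_settings(grid: HyperparamGrid) -> list[HyperparamSetting]:
    """Expand a grid into the ordered list of settings to evaluate."""
    if grid.method == "tsne":
        return [
            HyperparamSetting(method="tsne", perplexity=float(p))
            for p in grid.perplexity_values
        ]
    if grid.mode == "joint":
        return [
            HyperparamSetting(method="umap", n_neighbors=int(k), min_dist=float(d))
            for k, d in product(grid.n_neighbors_values, grid.min_dist_values)
        ]
    if grid.mode == "fixed":
        return [
            HyperparamSetting(
                method="umap",
                n_neighbors=int(grid.n_neighbors_values[0]),
                min_dist=float(grid.min_dist_values[0]),
            )
        ]
    # marginal: each hyperparameter sweeps while the other is anchored
    anchor_k = grid.anchor_n_neighbors or DEFAULT_ANCHOR_N_NEIGHBORS
    anchor_d = grid.anchor_min_dist or DEFAULT_ANCHOR_MIN_DIST
    settings = [
        HyperparamSetting(method="umap", n_neighbors=int(k), min_dist=float(anchor_d))
        for k in grid.n_neighbors_values
    ]
    settings += [
        HyperparamSetting(method="umap", n_neighbors=int(anchor_k), min_dist=float(d))
        for d in grid.min_dist_values
    ]
    return settings


def _setting_sort_key(setting: HyperparamSetting):
    if setting.method == "tsne":
        return (setting.perplexity,)
    return (setting.n_neighbors, setting.min_dist)


@dataclass
class OptimizationResult:
    """Grid-search outcome: one row per evaluated setting plus the choice."""

    rows: list[dict] = field(default_factory=list)
    best_setting: HyperparamSetting | None = None
    all_minimizers: list[HyperparamSetting] = field(default_factory=list)
    kneedle_setting: HyperparamSetting | None = None
    failed: list[tuple[HyperparamSetting, str]] = field(default_factory=list)

    @property
    def min_dubious(self) -> int:
        return min(r["n_dubious"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "setting": r["setting"].label(),
                "n_dubious": r["n_dubious"],
                "n_trustworthy": r["n_trustworthy"],
                "pct_dubious": r["pct_dubious"],
                "pct_trustworthy": r["pct_trustworthy"],
            }
            for r in self.rows
        ]
        return pd.DataFrame.from_records(
            records,
            columns=[
                "setting", "n_dubious", "n_trustworthy",
                "pct_dubious", "pct_trustworthy",
            ],
        )

    def dubious_curve(self) -> tuple[list[float], list[int]]:
        """(hyperparameter value, dubious count) pairs for a 1D sweep."""
        values = []
        for r in self.rows:
            s = r["setting"]
            values.append(s.perplexity if s.method == "tsne" else s.n_neighbors)
        return values, [r["n_dubious"] for r in self.rows]


def grid_search(
    matrix: GeneCellMatrix,
    cfg: RunConfig,
    grid: HyperparamGrid,
    kneedle: bool = False,
    keep_results: bool = False,
) -> OptimizationResult:
    """Evaluate every candidate setting and pick the dubious-count minimizer.

    The matrix is permuted once (permutation does not depend on the embedder
    setting) and both pre-embeddings are built once; each setting then embeds
    the original and permuted pre-embeddings with the shared embed seed.
    A setting that fails is logged, recorded and excluded. With ``kneedle``
    and a one-dimensional sweep, the elbow of the dubious-count curve is also
    reported. ``keep_results`` retains each setting's ReliabilityResult in
    the rows (memory scales with grid size).
    """
    settings = enumerate_settings(grid)
    pre = build_pre_embedding(matrix, cfg)
    pre_null = build_pre_embedding(permute_genes(matrix, cfg.permute_seed), cfg)

    result = OptimizationResult()
    for setting in settings:
        try:
            rel: ReliabilityResult = score_embedding(
                matrix, cfg, setting, pre=pre, pre_null=pre_null
            )
        except Exception as exc:  # record and move on
            warnings.warn(f"setting {setting.label()} failed: {exc}", stacklevel=2)
            result.failed.append((setting, str(exc)))
            continue
        row = {
            "setting": setting,
            "n_dubious": rel.n_dubious,
            "n_trustworthy": rel.n_trustworthy,
            "pct_dubious": rel.pct_dubious,
            "pct_trustworthy": rel.pct_trustworthy,
        }
        if keep_results:
            row["result"] = rel
        result.rows.append(row)
        logger.info("%s: %d dubious (%.2f%%)", setting.label(), rel.n_dubious, rel.pct_dubious)
    if not result.rows:
        raise ValidationError("every candidate setting failed")

    best_count = min(r["n_dubious"] for r in result.rows)
    minimizers = [r["setting"] for r in result.rows if r["n_dubious"] == best_count]
    minimizers.sort(key=_setting_sort_key)
    result.all_minimizers = minimizers
    result.best_setting = minimizers[0]
    if len(minimizers) > 1:
        logger.info(
            "%d settings tie at %d dubious; choosing the smallest: %s",
            len(minimizers), best_count, result.best_setting.label(),
        )

    if kneedle:
        values, counts = result.dubious_curve()
        is_1d = grid.method == "tsne"
        if grid.method == "umap" and grid.mode == "marginal":
            # apply kneedle to the n_neighbors sweep only
            k = len(grid.n_neighbors_values)
            values, counts = values[:k], counts[:k]
            is_1d = True
        if not is_1d:
            warnings.warn("kneedle applies to 1D sweeps only; skipping", stacklevel=2)
        else:
            chosen = kneedle_select(values, counts)
            if chosen is not None:
                for r in result.rows:
                    v = (
                        r["setting"].perplexity
                        if grid.method == "tsne"
                        else r["setting"].n_neighbors
                    )
                    if v == chosen:
                        result.kneedle_setting = r["setting"]
                        break
    return result


def kneedle_select(values, dubious_counts, sensitivity: float = 1.0):
    """Elbow of the dubious-count vs hyperparameter curve (kneedle).

    Both axes are min-max normalized; the difference between the normalized
    curve and the chord from the first to the last point is maximized. For
    the convex-decreasing curves that dubious counts typically form, the
    maximizer of the difference curve is the knee. With sensitivity S, a knee
    is only declared when the maximum difference exceeds S times the mean
    normalized x-spacing; a flat or linear curve therefore yields ``None``.
    """
    values = np.asarray(values, dtype=float)
    counts = np.asarray(dubious_counts, dtype=float)
    if values.size != counts.size:
        raise ValidationError("values and counts differ in length")
    if values.size < 3:
        raise ValidationError("kneedle needs at least 3 points")
    if np.any(np.diff(values) <= 0):
        raise ValidationError("values must be strictly increasing")
    if np.all(counts == counts[0]):
        warnings.warn("dubious counts are constant; no elbow", stacklevel=2)
        return None
    x = (values - values[0]) / (values[-1] - values[0])
    y = (counts - counts.min()) / (counts.max() - counts.min())
    # decreasing curve: flip so the chord from (0,0) to (1,1) applies
    diff = (1.0 - y) - x
    threshold = sensitivity * np.mean(np.diff(x))
    if diff.max() <= threshold:
        warnings.warn("difference curve has no pronounced knee", stacklevel=2)
        return None
    return float(values[int(np.argmax(diff))])
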