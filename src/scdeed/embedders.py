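"""Uniform contract for seeded 2D embedders (t-SNE, UMAP, passthrough).

Each adapter maps a pre-embedding (cells x d) to cells x 2 coordinates under
a hyperparameter setting and a fixed seed, with a determinism contract:
identical inputs, setting and seed give identical output. The t-SNE and UMAP
algorithms themselves are delegated to scikit-learn and umap-learn in their
deterministic single-threaded modes; the contribution here is the scoring of
their output, not the embedders.

Reliability scores computed downstream are invariant to rigid motions
(rotation/translation/reflection) of the 2D coordinates but NOT to
anisotropic rescaling; coordinates are used exactly as produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ValidationError
from .preembedding import PreEmbedding


@dataclass(frozen=True)
class HyperparamSetting:
    """One embedder hyperparameter setting.

    Exactly the fields of the method are set: ``perplexity`` for t-SNE,
    ``n_neighbors`` and ``min_dist`` for UMAP, none for the passthrough
    embedder (which returns the first two pre-embedding dimensions and exists
    for testing the identity case).
    """

    method: str
    perplexity: float | None = None
    n_neighbors: int | None = None
    min_dist: float | None = None

    def __post_init__(self) -> None:
        if self.method == "tsne":
            if self.perplexity is None or self.perplexity <= 0:
                raise ValidationError("t-SNE requires a positive perplexity")
            if self.n_neighbors is not None or self.min_dist is not None:
                raise ValidationError("UMAP fields set on a t-SNE setting")
        elif self.method == "umap":
            if self.n_neighbors is None or self.n_neighbors < 2:
                raise ValidationError("UMAP requires n_neighbors >= 2")
            if self.min_dist is None or not 0 < self.min_dist < 1:
                raise ValidationError("UMAP requires min_dist in (0, 1)")
            if self.perplexity is not None:
                raise ValidationError("perplexity set on a UMAP setting")
        elif self.method == "passthrough":
            if any(v is not None for v in (self.perplexity, self.n_neighbors, self.min_dist)):
                raise ValidationError("passthrough takes no hyperparameters")
        else:
            raise ValidationError(f"unknown embedding method {self.method!r}")

    def validate_for(self, n_cells: int) -> None:
        """Reject settings infeasible for ``n_cells`` before the expensive call."""
        if self.method == "tsne" and self.perplexity >= (n_cells - 1) / 3:
            raise ValidationError(
                f"perplexity {self.perplexity} infeasible: requires "
                f"perplexity < (n-1)/3 = {(n_cells - 1) / 3:.2f} for n = {n_cells}"
            )
        if self.method == "umap" and self.n_neighbors >= n_cells:
            raise ValidationError(
                f"n_neighbors {self.n_neighbors} must be < n = {n_cells}"
            )

    def label(self) -> str:
        if self.method == "tsne":
            return f"perplexity={self.perplexity:g}"
        if self.method == "umap":
            return f"n_neighbors={self.n_neighbors},min_dist={self.min_dist:g}"
        return "passthrough"

    def to_dict(self) -> dict:
        out = {"method": self.method}
        if self.method == "tsne":
            out["perplexity"] = self.perplexity
        elif self.method == "umap":
            out["n_neighbors"] = self.n_neighbors
            out["min_dist"] = self.min_dist
        return out


@dataclass
class Embedding2D:
    """Cells x 2 coordinates produced by an embedder; rows align with the
    pre-embedding's cell order."""

    coords: np.ndarray
    cell_ids: list[str]
    setting: HyperparamSetting
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("embedding must be a cells x 2 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def _embed_tsne(coords: np.ndarray, setting: HyperparamSetting, seed: int) -> np.ndarray:
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=2,
        perplexity=setting.perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
        n_jobs=1,
    )
    return np.asarray(tsne.fit_transform(coords), dtype=float)


def _embed_umap(coords: np.ndarray, setting: HyperparamSetting, seed: int) -> np.ndarray:
    import warnings

    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=setting.n_neighbors,
        min_dist=setting.min_dist,
        random_state=seed,  # forces the deterministic single-threaded path
    )
    with warnings.catch_warnings():
        # umap-learn warns that a fixed random_state disables parallelism
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(coords), dtype=float)


def _embed_passthrough(coords: np.ndarray, setting: HyperparamSetting, seed: int) -> np.ndarray:
    return coords[:, :2].copy()


_ADAPTERS = {
    "tsne": _embed_tsne,
    "umap": _embed_umap,
    "passthrough": _embed_passthrough,
}


def embed(pre: PreEmbedding, setting: HyperparamSetting, seed: int) -> Embedding2D:
    """Produce the 2D embedding of ``pre`` under ``setting`` with ``seed``.

    The same setting and seed are used for the original and the permuted
    pre-embedding within a run, so original and null scores differ only
    through the data.
    """
    setting.validate_for(pre.n_cells)
    coords = _ADAPTERS[setting.method](pre.coords, setting, seed)
    return Embedding2D(
        coords=coords, cell_ids=list(pre.cell_ids), setting=setting, seed=seed
    )
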