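"""Pre-embedding construction: gene-wise permutation and optional PCA.

The pre-embedding space is where "true" cell neighborhoods live: either the
top-K principal components of the expression matrix or a user-supplied
coordinate matrix (e.g. independent components or CyTOF markers). The
permuted dataset — each gene's values shuffled independently across cells —
destroys all cell-cell structure while preserving every gene's marginal
distribution, and is the basis of the null score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import ValidationError
from .io import GeneCellMatrix


@dataclass
class PreEmbedding:
    """Cells x dims coordinates defining pre-embedding neighbor order."""

    coords: np.ndarray
    cell_ids: list[str]
    source: str = "user_supplied"  # "pca" | "user_supplied"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValidationError("pre-embedding must be a cells x d matrix, d >= 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("pre-embedding contains non-finite values")
        self.cell_ids = [str(s) for s in self.cell_ids]
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("cell_ids do not match coordinate rows")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def permute_genes(matrix: GeneCellMatrix, permute_seed: int) -> GeneCellMatrix:
    """Shuffle each gene's values independently across cells.

    Each row of the output is a uniform random permutation of the
    corresponding input row, drawn independently per gene from a single
    generator seeded with ``permute_seed``. Gene and cell identifiers are
    unchanged; every gene's marginal distribution is preserved exactly.
    """
    rng = np.random.default_rng(permute_seed)
    permuted = rng.permuted(matrix.values, axis=1)
    return GeneCellMatrix(
        values=permuted,
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
    )


def compute_pca(
    matrix: GeneCellMatrix,
    num_pcs: int,
    center: bool = True,
    scale: bool = False,
) -> PreEmbedding:
    """Top-K principal-component scores of the cells.

    Genes are centered by default and optionally scaled to unit variance;
    zero-variance genes are dropped with a warning when scaling. Components
    are ordered by decreasing explained variance and each component's sign is
    fixed so that its largest-magnitude gene loading is positive, making the
    result deterministic. Reliability scores depend only on distances and are
    therefore invariant to this sign convention.
    """
    g, n = matrix.values.shape
    limit = min(g, n - 1) if center else min(g, n)
    if not 1 <= num_pcs <= limit:
        raise ValidationError(
            f"num_pcs must be in [1, {limit}] for a {g} x {n} matrix, got {num_pcs}"
        )
    X = matrix.values.T.astype(float)  # cells x genes
    if scale:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} zero-variance gene(s) before scaling",
                stacklevel=2,
            )
            X = X[:, keep]
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd
    elif center:
        X = X - X.mean(axis=0)
    # economy SVD: scores = U * s, loadings in rows of Vt
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :num_pcs] * s[:num_pcs]
    for k in range(num_pcs):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    return PreEmbedding(coords=scores, cell_ids=list(matrix.cell_ids), source="pca")


def build_pre_embedding(matrix: GeneCellMatrix, cfg) -> PreEmbedding:
    """Pre-embedding per config: PCA with K components, or the matrix itself.

    With ``cfg.num_pcs is None`` the (transposed) matrix is used directly as
    cells x features coordinates, as when markers or externally computed
    components are supplied.
    """
    if cfg.num_pcs is None:
        return PreEmbedding(
            coords=matrix.values.T.copy(),
            cell_ids=list(matrix.cell_ids),
            source="user_supplied",
        )
    return compute_pca(matrix, cfg.num_pcs, center=cfg.center, scale=cfg.scale)
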