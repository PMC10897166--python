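"""Run configuration shared by the scoring and optimization pipelines."""

from __future__ import annotations

from dataclasses import dataclass


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class RunConfig:
    """Configuration of one scDEED run.

    Parameters
    ----------
    num_pcs
        Number of principal components K for the pre-embedding space, or
        ``None`` to use the supplied matrix (transposed to cells x features)
        directly, as when the pre-embedding space is a set of markers or
        externally computed components.
    similarity_percent
        The similarity percent x in (0, 100]: the percentage of all cells
        counted as each cell's ordered neighborhood. Default 50, the method's
        only hyperparameter.
    embed_method
        ``"tsne"`` or ``"umap"`` (``"passthrough"`` is accepted for testing).
    embed_seed, permute_seed
        Random seeds for the 2D embedder and the gene-wise permutation.
        Both default to 100, the embedding seed convention of the method.
    dubious_percentile, trustworthy_percentile
        Percentiles of the null reliability-score distribution below/above
        which a cell embedding is called dubious/trustworthy (defaults 5, 95).
    center, scale
        PCA preprocessing flags: center genes (default on), scale genes to
        unit variance (default off; upstream pipelines usually scale already).
    """

    num_pcs: int | None = None
    similarity_percent: float = 50.0
    embed_method: str = "tsne"
    embed_seed: int = 100
    permute_seed: int = 100
    dubious_percentile: float = 5.0
    trustworthy_percentile: float = 95.0
    center: bool = True
    scale: bool = False

    def __post_init__(self) -> None:
        if self.num_pcs is not None and self.num_pcs < 1:
            raise ValidationError("num_pcs must be a positive integer or None")
        if not 0.0 < self.similarity_percent <= 100.0:
            raise ValidationError("similarity_percent must be in (0, 100]")
        if self.embed_method not in ("tsne", "umap", "passthrough"):
            raise ValidationError(f"unknown embed_method: {self.embed_method!r}")
        for name in ("dubious_percentile", "trustworthy_percentile"):
            p = getattr(self, name)
            if not 0.0 < p < 100.0:
                raise ValidationError(f"{name} must be in (0, 100)")
        if self.dubious_percentile >= self.trustworthy_percentile:
            raise ValidationError(
                "dubious_percentile must be smaller than trustworthy_percentile"
            )
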