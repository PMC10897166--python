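"""Synthetic clustered expression matrices with controllable geometry.

The generator emulates the role of a simulated scRNA-seq benchmark: k cell
types whose mean expression vectors sit at the vertices of a regular simplex
in gene space, with the edge length expressed in units of the within-cluster
standard deviation (the ``separation`` parameter). At separation 0 the
clusters are indistinguishable by construction; at separation ~8 they are
cleanly separable in PC space. Noise is Gaussian by default — the downstream
statistic consumes only distances, and Gaussian noise keeps ``separation``
directly interpretable — with a log1p negative-binomial option for
count-like realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ValidationError
from .io import GeneCellMatrix
from .metrics import LabeledCells


@dataclass
class SyntheticSpec:
    """Parameters of one simulated dataset.

    ``separation`` is the Euclidean distance between any two cluster mean
    vectors divided by ``noise_sd``; ``cluster_proportions`` defaults to
    equal sizes.
    """

    n_cells: int = 600
    n_genes: int = 1000
    k_clusters: int = 3
    cluster_proportions: tuple = ()
    separation: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0
    noise: str = "gaussian"  # "gaussian" | "lognb"

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValidationError("k_clusters must be >= 1")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_cells < 4 or self.n_genes < max(2, self.k_clusters):
            raise ValidationError("matrix too small for the requested clusters")
        if not self.cluster_proportions:
            self.cluster_proportions = tuple([1.0 / self.k_clusters] * self.k_clusters)
        self.cluster_proportions = tuple(float(p) for p in self.cluster_proportions)
        if len(self.cluster_proportions) != self.k_clusters:
            raise ValidationError("need one proportion per cluster")
        if any(p <= 0 for p in self.cluster_proportions):
            raise ValidationError("proportions must be positive")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-8:
            raise ValidationError("proportions must sum to 1")
        if self.noise not in ("gaussian", "lognb"):
            raise ValidationError(f"unknown noise model {self.noise!r}")


def _cluster_sizes(spec: SyntheticSpec) -> list[int]:
    # largest-remainder apportionment so sizes sum exactly to n_cells
    exact = np.asarray(spec.cluster_proportions) * spec.n_cells
    sizes = np.floor(exact).astype(int)
    remainder = spec.n_cells - sizes.sum()
    order = np.argsort(-(exact - sizes), kind="stable")
    for j in order[:remainder]:
        sizes[j] += 1
    if np.any(sizes == 0):
        raise ValidationError("a cluster received 0 cells; adjust proportions")
    return sizes.tolist()


def simulate_clusters(spec: SyntheticSpec) -> tuple[GeneCellMatrix, LabeledCells]:
    """Generate a genes x cells matrix and its ground-truth cluster labels.

    Cluster means are a shared baseline plus offsets along k random
    orthonormal gene-space directions, scaled so every pair of cluster means
    is exactly ``separation * noise_sd`` apart. Cell values are the cluster
    mean plus independent noise. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g, n, k = spec.n_genes, spec.n_cells, spec.k_clusters
    baseline = rng.gamma(shape=2.0, scale=1.0, size=g)

    # orthonormal directions -> pairwise mean distance s*sqrt(2) for s*u_j
    raw = rng.normal(size=(g, k))
    q, _ = np.linalg.qr(raw)
    scale = spec.separation * spec.noise_sd / np.sqrt(2.0)
    means = baseline[:, None] + scale * q[:, :k]  # genes x clusters

    sizes = _cluster_sizes(spec)
    assignments = np.repeat(np.arange(k), sizes)
    if spec.noise == "gaussian":
        values = means[:, assignments] + rng.normal(0.0, spec.noise_sd, size=(g, n))
    else:
        # count-like option: NB counts around exp-transformed means, log1p'd
        mu = np.exp(np.clip(means[:, assignments] * 0.25, None, 8.0))
        theta = 10.0
        p = theta / (theta + mu)
        counts = rng.negative_binomial(theta, p)
        values = np.log1p(counts)

    matrix = GeneCellMatrix(
        values=values,
        gene_ids=[f"g{i + 1:05d}" for i in range(g)],
        cell_ids=[f"c{j + 1:05d}" for j in range(n)],
    )
    labels = LabeledCells(
        cell_ids=list(matrix.cell_ids),
        labels=[f"cluster{a + 1}" for a in assignments],
    )
    return matrix, labels
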