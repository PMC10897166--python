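import numpy as np
import pytest

from scdeed import RunConfig, SyntheticSpec, simulate_clusters


@pytest.fixture(scope="session")
def clusters600():
    """Well-separated 3-cluster study fixture: n=600, separation 8 sd."""
    spec = SyntheticSpec(
        n_cells=600, n_genes=1000, k_clusters=3, separation=8.0, seed=1
    )
    return simulate_clusters(spec)


@pytest.fixture(scope="session")
def clusters300():
    """Smaller copy of the clean fixture for per-setting experiments."""
    spec = SyntheticSpec(
        n_cells=300, n_genes=1000, k_clusters=3, separation=8.0, seed=1
    )
    return simulate_clusters(spec)


@pytest.fixture(scope="session")
def hard_clusters600():
    """Moderately separated 8-cluster fixture in which dubious embeddings
    actually occur, used for the sensitivity analyses."""
    spec = SyntheticSpec(
        n_cells=600, n_genes=1000, k_clusters=8, separation=3.0, seed=1
    )
    return simulate_clusters(spec)


@pytest.fixture
def cfg_pcs5():
    return RunConfig(num_pcs=5)


# ---------------------------------------------------------------------------
# Independent brute-force oracle: explicit Python loops, full sorts and the
# textbook correlation formula. Deliberately shares no code with the package.
# ---------------------------------------------------------------------------

def _dist(p, q):
    return sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5


def brute_force_neighbors(coords, cell, m):
    pairs = [
        (_dist(coords[cell], coords[j]), j)
        for j in range(len(coords))
        if j != cell
    ]
    pairs.sort()  # (distance, index): index breaks distance ties
    return [j for _, j in pairs[:m]]


def _brute_pearson(u, v):
    k = len(u)
    if all(a == u[0] for a in u) or all(b == v[0] for b in v):
        return float("nan")
    mu = sum(u) / k
    mv = sum(v) / k
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = sum((a - mu) ** 2 for a in u) ** 0.5
    sv = sum((b - mv) ** 2 for b in v) ** 0.5
    if su == 0 or sv == 0:
        return float("nan")
    return cov / (su * sv)


def brute_force_scores(pre, emb, similarity_percent):
    pre = np.asarray(pre, dtype=float).tolist()
    emb = np.asarray(emb, dtype=float).tolist()
    n = len(pre)
    m = int(np.floor(similarity_percent / 100.0 * n + 0.5))
    m = max(2, min(m, n - 1))
    scores = []
    for i in range(n):
        A = brute_force_neighbors(pre, i, m)
        B = brute_force_neighbors(emb, i, m)
        v_pre = [_dist(emb[i], emb[j]) for j in A]
        v_emb = [_dist(emb[i], emb[j]) for j in B]
        scores.append(_brute_pearson(v_pre, v_emb))
    return np.array(scores)
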