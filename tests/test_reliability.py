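import numpy as np
import pytest

from scdeed import (
    GeneCellMatrix,
    HyperparamSetting,
    RunConfig,
    ValidationError,
    classify,
    compute_pca,
    embed,
    neighborhood_size,
    null_reliability_scores,
    ordered_neighbors,
    permute_genes,
    reliability_score,
    reliability_scores_all,
    simulate_clusters,
)
from scdeed.reliability import DegenerateNullError
from scdeed.synthetic import SyntheticSpec

from conftest import brute_force_neighbors, brute_force_scores


# ---------------------------------------------------------------- neighbors

@pytest.mark.parametrize(
    "x, n, expected",
    [(50, 100, 50), (50, 7, 4), (100, 100, 99), (1, 100, 2), (100, 4, 3)],
)
def test_neighborhood_size_rounds_half_up_and_clamps(x, n, expected):
    assert neighborhood_size(x, n) == expected


def test_ordered_neighbors_by_distance():
    coords = np.array([[0.0], [1.0], [3.0], [7.0]])
    np.testing.assert_array_equal(ordered_neighbors(coords, 0, 2), [1, 2])


def test_ordered_neighbors_tie_broken_by_index():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
    np.testing.assert_array_equal(ordered_neighbors(coords, 0, 2), [1, 2])


def test_ordered_neighbors_excludes_self_and_validates_m():
    coords = np.random.default_rng(0).normal(size=(10, 2))
    assert 3 not in ordered_neighbors(coords, 3, 9)
    with pytest.raises(ValidationError):
        ordered_neighbors(coords, 0, 10)


def test_ordered_neighbors_matches_full_sort_oracle():
    rng = np.random.default_rng(11)
    coords = rng.normal(size=(50, 3))
    for cell in (0, 17, 49):
        np.testing.assert_array_equal(
            ordered_neighbors(coords, cell, 25),
            brute_force_neighbors(coords.tolist(), cell, 25),
        )


# ------------------------------------------------------------------ scores

def test_passthrough_on_2d_pre_embedding_scores_one():
    rng = np.random.default_rng(1)
    pre = rng.normal(size=(40, 2))
    scores = reliability_scores_all(pre, pre.copy(), 50)
    np.testing.assert_allclose(scores, 1.0, atol=1e-12)


def test_exactly_reversed_neighbor_order_scores_minus_one():
    # pre-space order (a, b, c) has 2D distances (3, 2, 1); the 2D order is
    # the exact reversal, so the two distance vectors are perfectly
    # negatively related
    emb = np.array([[0.0, 0.0], [3.0, 0.0], [-2.0, 0.0], [1.0, 0.0]])
    pre = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    assert reliability_score(pre, emb, cell=0, m=3) == pytest.approx(-1.0)


def test_worked_correlation_value():
    # pre order (b, a, c) gives v_pre = (2, 1, 4); 2D order (a, b, c) gives
    # v_emb = (1, 2, 4); Pearson r = 11/14 by the covariance formula
    pre = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    emb = np.array([[0.0, 0.0], [1.0, 0.0], [-2.0, 0.0], [4.0, 0.0]])
    assert reliability_score(pre, emb, cell=0, m=3) == pytest.approx(11 / 14, abs=1e-12)


def test_equidistant_neighbors_score_undefined():
    # cell 0 sits at the center of a square in 2D: every neighbor distance
    # is 1, the distance vector is constant, and the correlation undefined
    emb = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
    pre = np.random.default_rng(2).normal(size=(5, 3))
    scores = reliability_scores_all(pre, emb, 50)
    assert np.isnan(scores[0])


def test_scores_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(6):
        n = int(rng.integers(10, 61))
        d = int(rng.choice([2, 5]))
        x = float(rng.choice([30, 50, 80]))
        pre = rng.normal(size=(n, d))
        emb = rng.normal(size=(n, 2))
        got = reliability_scores_all(pre, emb, x)
        want = brute_force_scores(pre, emb, x)
        np.testing.assert_allclose(got, want, atol=1e-10)


def test_scores_invariant_under_rigid_motion_of_embedding():
    rng = np.random.default_rng(8)
    pre = rng.normal(size=(60, 4))
    emb = rng.normal(size=(60, 2))
    theta = 1.234
    rotation = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    reflection = np.array([[1.0, 0.0], [0.0, -1.0]])
    moved = emb @ rotation @ reflection + np.array([5.0, -3.0])
    np.testing.assert_allclose(
        reliability_scores_all(pre, emb, 50),
        reliability_scores_all(pre, moved, 50),
        atol=1e-9,
    )


def test_scores_invariant_under_gene_reordering():
    matrix, _ = simulate_clusters(
        SyntheticSpec(n_cells=60, n_genes=120, k_clusters=3, separation=5.0, seed=4)
    )
    rng = np.random.default_rng(9)
    shuffled = GeneCellMatrix(
        values=matrix.values[rng.permutation(matrix.n_genes)],
        cell_ids=list(matrix.cell_ids),
    )
    pre_a = compute_pca(matrix, 4)
    pre_b = compute_pca(shuffled, 4)
    emb = np.random.default_rng(10).normal(size=(60, 2))
    np.testing.assert_allclose(
        reliability_scores_all(pre_a.coords, emb, 50),
        reliability_scores_all(pre_b.coords, emb, 50),
        atol=1e-9,
    )


def test_embedding_order_distance_vector_is_nondecreasing():
    rng = np.random.default_rng(12)
    emb = rng.normal(size=(30, 2))
    for cell in range(30):
        B = ordered_neighbors(emb, cell, 15)
        v_emb = np.linalg.norm(emb[B] - emb[cell], axis=1)
        assert np.all(np.diff(v_emb) >= 0)


def test_misaligned_inputs_rejected():
    with pytest.raises(ValidationError):
        reliability_scores_all(np.zeros((10, 2)), np.zeros((9, 2)), 50)


# ------------------------------------------------------------------- null

@pytest.fixture(scope="module")
def null_setup():
    matrix, _ = simulate_clusters(
        SyntheticSpec(n_cells=120, n_genes=300, k_clusters=3, separation=8.0, seed=5)
    )
    cfg = RunConfig(num_pcs=4)
    setting = HyperparamSetting(method="tsne", perplexity=30.0)
    return matrix, cfg, setting


def test_null_scores_deterministic_end_to_end(null_setup):
    matrix, cfg, setting = null_setup
    a = null_reliability_scores(matrix, cfg, setting)
    b = null_reliability_scores(matrix, cfg, setting)
    np.testing.assert_array_equal(a, b)
    valid = a[~np.isnan(a)]
    assert np.all(valid >= -1) and np.all(valid <= 1)


def test_null_distribution_sits_below_original_scores(null_setup):
    matrix, cfg, setting = null_setup
    pre = compute_pca(matrix, cfg.num_pcs)
    emb = embed(pre, setting, cfg.embed_seed)
    original = reliability_scores_all(pre, emb, cfg.similarity_percent)
    p90 = np.nanpercentile(original, 90)
    for permute_seed in (100, 101, 102, 103, 104):
        cfg_s = RunConfig(num_pcs=cfg.num_pcs, permute_seed=permute_seed)
        null = null_reliability_scores(matrix, cfg_s, setting)
        assert np.nanmedian(null) < p90


# --------------------------------------------------------------- classify

def test_classify_worked_quantile_example():
    null = np.arange(0.1, 1.01, 0.1)
    result = classify(np.array([0.10, 0.50, 0.96]), null)
    assert result.dubious_cutoff == pytest.approx(0.145, abs=1e-12)
    assert result.trustworthy_cutoff == pytest.approx(0.955, abs=1e-12)
    assert list(result.labels) == ["dubious", "intermediate", "trustworthy"]


def test_classify_self_calibration():
    rng = np.random.default_rng(13)
    null = rng.uniform(-1, 1, size=100)
    result = classify(null, null)
    n = len(null)
    assert abs(result.n_dubious / n - 0.05) <= 1.0 / n
    assert abs(result.n_trustworthy / n - 0.05) <= 1.0 / n


def test_classify_dominant_scores_all_trustworthy():
    null = np.linspace(-0.9, 0.9, 50)
    result = classify(np.ones(20), null)
    assert result.n_trustworthy == 20
    assert result.pct_trustworthy == 100.0


def test_classify_undefined_scores_labeled_and_null_nans_dropped():
    null = np.array([0.1, 0.2, np.nan, 0.3, 0.4, np.nan])
    scores = np.array([np.nan, 0.25, 0.45])
    result = classify(scores, null)
    assert result.labels[0] == "undefined"
    assert result.n_undefined == 1
    expected_cutoffs = np.percentile([0.1, 0.2, 0.3, 0.4], [5, 95])
    assert result.dubious_cutoff == pytest.approx(expected_cutoffs[0])
    assert result.trustworthy_cutoff == pytest.approx(expected_cutoffs[1])


def test_classify_degenerate_null_rejected():
    with pytest.raises(DegenerateNullError):
        classify(np.array([0.5]), np.array([np.nan, np.nan]))


def test_score_exactly_at_cutoff_takes_extreme_label():
    null = np.linspace(0, 1, 11)  # P5 = 0.05, P95 = 0.95
    result = classify(np.array([0.05, 0.95, 0.5]), null)
    assert list(result.labels) == ["dubious", "trustworthy", "intermediate"]


def test_structured_data_far_exceeds_null_calibration(clusters300, cfg_pcs5):
    # on well-clustered data many more than 5% of cells are trustworthy and
    # far fewer than 5% dubious: the label fractions are data-dependent
    from scdeed import score_embedding

    matrix, _ = clusters300
    setting = HyperparamSetting(method="tsne", perplexity=30.0)
    result = score_embedding(matrix, cfg_pcs5, setting)
    assert result.pct_trustworthy > 30.0
    assert result.pct_dubious < 5.0
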