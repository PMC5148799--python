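import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rexpress import (
    DegenerateRatioError,
    EnrichmentCriteria,
    call_enriched,
    compute_rex_scores,
)

from conftest import make_matrix, random_matrix

LAYOUT = [("pituitary", 3), ("liver", 3), ("heart", 3)]


def test_uniform_gene_has_zero_ratio_and_is_not_enriched():
    """A gene with one identical FPKM value in every sample of every tissue
    has log2_ratio exactly 0 and is never called enriched."""
    rng = np.random.default_rng(0)
    values = np.exp2(rng.normal(3, 1, (6, 9)))
    values[0, :] = 7.5
    matrix = make_matrix(values, [f"g{i}" for i in range(6)], LAYOUT)
    scores = compute_rex_scores(matrix, "pituitary", 21).set_index("gene_id")
    assert scores.loc["g0", "log2_ratio"] == 0.0
    assert not scores.loc["g0", "enriched"]


def test_log2_ratio_oracle_small_pseudocount():
    """focal_max 100, other_median 1: the ratio approaches log2(100) ≈ 6.644
    as the pseudocount vanishes."""
    values = np.ones((3, 9))
    values[0, 0:3] = [100.0, 50.0, 10.0]  # focal samples; max = 100
    values[1] = np.linspace(1, 9, 9)
    values[2] = np.linspace(2, 18, 9)
    matrix = make_matrix(values, ["hot", "a", "b"], LAYOUT)
    criteria = EnrichmentCriteria(pseudocount=1e-9)
    scores = compute_rex_scores(matrix, "pituitary", 21, criteria).set_index("gene_id")
    assert scores.loc["hot", "focal_max"] == 100.0
    assert scores.loc["hot", "other_median"] == 1.0
    assert scores.loc["hot", "log2_ratio"] == pytest.approx(math.log2(100), abs=1e-6)


def five_gene_matrix():
    """Five genes engineered to log2 ratios {0, 0, 0, 0, 10}."""
    values = np.ones((5, 9))
    for i, base in enumerate((8.0, 4.0, 2.0, 1.0)):
        values[i, :] = base
    values[4, 0:3] = 1024.0  # focal
    values[4, 3:] = 1.0
    return make_matrix(values, [f"g{i}" for i in range(5)], LAYOUT)


def test_z_standardization_hand_oracle():
    """Ratios {0,0,0,0,10}: mean 2, sample sd sqrt(20), so the extreme gene
    scores z = 8/sqrt(20) ≈ 1.789 — below the 2-SD threshold, hence not
    enriched despite the huge ratio."""
    criteria = EnrichmentCriteria(pseudocount=1e-9)
    scores = compute_rex_scores(
        five_gene_matrix(), "pituitary", 21, criteria
    ).set_index("gene_id")
    np.testing.assert_allclose(
        scores["log2_ratio"].to_numpy(), [0, 0, 0, 0, 10], atol=1e-6
    )
    assert scores.loc["g4", "z_score"] == pytest.approx(8 / math.sqrt(20), abs=1e-6)
    assert not scores["enriched"].any()


def test_call_enriched_applies_joint_rule():
    scores = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "z_score": [2.5, 2.5, 1.5],
            "p_value": [0.01, 0.2, 0.001],
        }
    )
    picked = call_enriched(scores, EnrichmentCriteria(), label="toy")
    assert picked.genes == {"a"}
    assert picked.label == "toy"


def test_call_enriched_empty_flag_set():
    scores = pd.DataFrame(
        {"gene_id": ["a"], "z_score": [0.5], "p_value": [0.5]}
    )
    assert len(call_enriched(scores, EnrichmentCriteria())) == 0
    with pytest.raises(ValueError, match="empty"):
        call_enriched(scores.iloc[:0], EnrichmentCriteria())


def test_welch_p_matches_scipy_reference():
    rng = np.random.default_rng(3)
    matrix = random_matrix(rng, n_genes=12)
    criteria = EnrichmentCriteria()
    scores = compute_rex_scores(matrix, "pituitary", 21, criteria)
    eps = criteria.pseudocount
    focal = np.log2(matrix.values_for(matrix.select_samples(tissue="pituitary", day=21)) + eps)
    other = np.log2(matrix.values_for(matrix.select_samples(exclude_tissue="pituitary", day=21)) + eps)
    for i, gene in enumerate(matrix.gene_ids):
        expected = stats.ttest_ind(
            focal.loc[gene], other.loc[gene], equal_var=False
        ).pvalue
        assert scores["p_value"][i] == pytest.approx(expected, rel=1e-12)


def test_errors_on_bad_inputs():
    rng = np.random.default_rng(1)
    matrix = random_matrix(rng)
    with pytest.raises(ValueError, match="day 99"):
        compute_rex_scores(matrix, "pituitary", 99)
    with pytest.raises(ValueError, match="focal tissue"):
        compute_rex_scores(matrix, "brain", 21)
    uniform = make_matrix(np.full((4, 9), 5.0), list("abcd"), LAYOUT)
    with pytest.raises(DegenerateRatioError, match="degenerate"):
        compute_rex_scores(uniform, "pituitary", 21)
    too_few = make_matrix(np.ones((2, 4)) * [[1, 2, 3, 4]], ["x", "y"],
                          [("pituitary", 3), ("liver", 1)])
    with pytest.raises(ValueError, match="non-focal"):
        compute_rex_scores(too_few, "pituitary", 21)


def test_single_focal_replicate_leaves_p_undefined():
    rng = np.random.default_rng(2)
    values = np.exp2(rng.normal(3, 1, (5, 7)))
    matrix = make_matrix(values, [f"g{i}" for i in range(5)],
                         [("pituitary", 1), ("liver", 3), ("heart", 3)])
    scores = compute_rex_scores(matrix, "pituitary", 21)
    assert scores["p_value"].isna().all()
    assert not scores["enriched"].any()


def test_scale_invariance_over_random_matrices():
    """Multiplying all FPKM by c > 0 (with the pseudocount scaled by c)
    leaves z-scores, p-values and the enriched set unchanged."""
    rng = np.random.default_rng(42)
    for trial in range(100):
        matrix = random_matrix(rng, n_genes=15)
        c = float(rng.uniform(0.01, 100))
        scaled = make_matrix(
            matrix.values.to_numpy() * c, matrix.gene_ids,
            [("pituitary", 4), ("liver", 3), ("heart", 3)],
        )
        base = compute_rex_scores(matrix, "pituitary", 21, EnrichmentCriteria(pseudocount=0.1))
        scal = compute_rex_scores(scaled, "pituitary", 21, EnrichmentCriteria(pseudocount=0.1 * c))
        np.testing.assert_allclose(base["z_score"], scal["z_score"], atol=1e-9)
        np.testing.assert_allclose(base["p_value"], scal["p_value"], atol=1e-9)
        assert (base["enriched"] == scal["enriched"]).all()
        np.testing.assert_allclose(
            np.diff(base["log2_ratio"]), np.diff(scal["log2_ratio"]), atol=1e-9
        )


def test_monotonicity_in_focal_values():
    """Raising only the focal-tissue values of one gene never decreases its
    z-score."""
    rng = np.random.default_rng(7)
    layout = [("pituitary", 4), ("liver", 3), ("heart", 3)]
    for trial in range(100):
        matrix = random_matrix(rng, n_genes=12)
        gene_idx = int(rng.integers(0, 12))
        factor = float(rng.uniform(1.0, 50.0))
        bumped_values = matrix.values.to_numpy().copy()
        bumped_values[gene_idx, 0:4] *= factor
        bumped = make_matrix(bumped_values, matrix.gene_ids, layout)
        z0 = compute_rex_scores(matrix, "pituitary", 21)["z_score"][gene_idx]
        z1 = compute_rex_scores(bumped, "pituitary", 21)["z_score"][gene_idx]
        assert z1 >= z0 - 1e-12


def test_gene_permutation_equivariance():
    rng = np.random.default_rng(9)
    matrix = random_matrix(rng, n_genes=10)
    perm = rng.permutation(10)
    permuted = make_matrix(
        matrix.values.to_numpy()[perm], [matrix.gene_ids[i] for i in perm],
        [("pituitary", 4), ("liver", 3), ("heart", 3)],
    )
    a = compute_rex_scores(matrix, "pituitary", 21).set_index("gene_id").sort_index()
    b = compute_rex_scores(permuted, "pituitary", 21).set_index("gene_id").sort_index()
    pd.testing.assert_frame_equal(a, b)


def test_day_independence():
    """Scores for one day do not change when another day's samples do."""
    rng = np.random.default_rng(13)
    n = 8
    base21 = np.exp2(rng.normal(3, 1.5, (n, 9)))
    day42 = np.exp2(rng.normal(3, 1.5, (n, 9)))
    genes = [f"g{i}" for i in range(n)]

    def two_day_matrix(day42_values):
        import pandas as pd
        from rexpress import ExpressionMatrix, SampleMeta

        meta, cols = [], {}
        for day, block in ((21, base21), (42, day42_values)):
            for j, (tissue, rep) in enumerate(
                [(t, r) for t, k in [("pituitary", 3), ("liver", 3), ("heart", 3)] for r in range(1, k + 1)]
            ):
                sid = f"{tissue}_d{day}_r{rep}"
                cols[sid] = block[:, j]
                meta.append(SampleMeta(sid, tissue, day, rep))
        return ExpressionMatrix(pd.DataFrame(cols, index=genes), meta)

    m1 = two_day_matrix(day42)
    m2 = two_day_matrix(day42 * 3.7)
    s1 = compute_rex_scores(m1, "pituitary", 21)
    s2 = compute_rex_scores(m2, "pituitary", 21)
    pd.testing.assert_frame_equal(s1, s2)


def test_bh_mode_is_more_conservative():
    rng = np.random.default_rng(21)
    matrix = random_matrix(rng, n_genes=40)
    raw = compute_rex_scores(matrix, "pituitary", 21, EnrichmentCriteria())
    bh = compute_rex_scores(
        matrix, "pituitary", 21,
        EnrichmentCriteria(multiple_testing="benjamini_hochberg"),
    )
    assert "p_adjusted" in bh.columns
    assert (bh["p_adjusted"].dropna() >= bh["p_value"].dropna() - 1e-15).all()
    assert set(bh.loc[bh["enriched"], "gene_id"]) <= set(raw.loc[raw["enriched"], "gene_id"])


def test_ratio_normal_mode_matches_z():
    rng = np.random.default_rng(23)
    matrix = random_matrix(rng, n_genes=25)
    scores = compute_rex_scores(
        matrix, "pituitary", 21, EnrichmentCriteria(t_test="ratio_normal")
    )
    expected = 2 * stats.norm.sf(np.abs(scores["z_score"]))
    np.testing.assert_allclose(scores["p_value"], expected, atol=1e-12)


def test_min_focal_fpkm_floor():
    rng = np.random.default_rng(29)
    matrix = random_matrix(rng, n_genes=30)
    floored = compute_rex_scores(
        matrix, "pituitary", 21, EnrichmentCriteria(min_focal_fpkm=1e9)
    )
    assert not floored["enriched"].any()


def test_per_tissue_median_mode():
    # liver medians 4 (one outlier replicate), heart 10: median of per-tissue
    # medians is 7, while the pooled six-sample median is 10
    values = np.ones((2, 9))
    values[0, 0:3] = 50.0
    values[0, 3:6] = [4.0, 4.0, 1000.0]  # liver
    values[0, 6:9] = 10.0                # heart
    matrix = make_matrix(values, ["g0", "g1"], LAYOUT)
    pooled = compute_rex_scores(
        matrix, "pituitary", 21, EnrichmentCriteria(pseudocount=1e-9)
    )
    per_tissue = compute_rex_scores(
        matrix, "pituitary", 21,
        EnrichmentCriteria(pseudocount=1e-9, median_mode="per_tissue"),
    )
    assert pooled.loc[0, "other_median"] == pytest.approx(10.0)
    assert per_tissue.loc[0, "other_median"] == pytest.approx(7.0)
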