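"""Discovery cascade: variable genes, consensus NMF, SAM, PAM, filters."""

import numpy as np
import pandas as pd
import pytest

from crisforge.core_io import ExpressionMatrix, ValidationError, zscore_samples
from crisforge.discovery import (
    ConsensusResult,
    _cophenetic_coefficient,
    assign_nonredundant,
    best_k,
    filter_cascade_report,
    nmf_consensus,
    pam_train,
    sam_multiclass,
    select_variable_genes,
    silhouette_filter,
    stromal_filter,
    PamModel,
)
from crisforge.synthetic_data import SubtypeModel, simulate_expression


# --- variable genes ---------------------------------------------------------


def test_select_variable_genes_threshold():
    rng = np.random.default_rng(0)
    values = np.vstack([rng.normal(0, 1.0, 50), rng.normal(0, 0.2, 50)])
    m = ExpressionMatrix(["A", "B"], [f"s{j}" for j in range(50)], values)
    assert select_variable_genes(m, 0.8) == ["A"]
    assert select_variable_genes(m, 0.0) == ["A", "B"]


def test_select_variable_genes_recovers_planted(small_model, small_cohort):
    matrix, _, _ = small_cohort
    planted = {g for genes in small_model.marker_genes().values() for g in genes}
    kept = set(select_variable_genes(matrix, 0.8))
    assert planted <= kept


def test_select_variable_genes_empty_errors(random_matrix):
    with pytest.raises(ValidationError, match="threshold"):
        select_variable_genes(random_matrix, 1e6)


# --- consensus NMF ----------------------------------------------------------


def test_single_run_consensus_is_binary(small_cohort):
    matrix = zscore_samples(small_cohort[0])
    (res,) = nmf_consensus(matrix, K_range=[3], n_runs=1, seed=0)
    off = res.consensus[~np.eye(matrix.n_samples, dtype=bool)]
    assert set(np.unique(off)) <= {0.0, 1.0}


def test_block_diagonal_consensus_has_unit_cophenetic():
    consensus = np.kron(np.eye(3), np.ones((4, 4)))
    assert _cophenetic_coefficient(consensus) == pytest.approx(1.0)


def test_cophenetic_recovers_planted_k():
    model = SubtypeModel(n_classes=3, markers_per_class=15, n_background_genes=60,
                        n_stromal_genes=0, seed=5)
    matrix, _, _ = simulate_expression(model, 15)
    sub = matrix.subset_genes(select_variable_genes(matrix, 0.8))
    results = nmf_consensus(zscore_samples(sub), K_range=range(2, 6), n_runs=10, seed=5)
    assert best_k(results).K == 3
    for r in results:
        assert 0.0 <= r.cophenetic <= 1.0


def test_k_too_large_rejected(small_cohort):
    matrix = zscore_samples(small_cohort[0])
    with pytest.raises(ValidationError):
        nmf_consensus(matrix, K_range=[matrix.n_samples], n_runs=1)


# --- silhouette -------------------------------------------------------------


def _consensus_result(consensus, labels):
    return ConsensusResult(
        K=len(set(labels)), consensus=consensus,
        cophenetic=1.0, hard_labels=np.asarray(labels),
        sample_ids=[f"s{i}" for i in range(len(labels))],
    )


def test_silhouette_keeps_separated_blocks():
    consensus = np.kron(np.eye(2), np.ones((4, 4)))
    res = _consensus_result(consensus, [1] * 4 + [2] * 4)
    core, dropped = silhouette_filter(res)
    assert dropped == [] and len(core) == 8


def test_silhouette_drops_misplaced_sample():
    consensus = np.kron(np.eye(2), np.ones((4, 4)))
    # sample 0 nearly identical to the other cluster, distant from its own
    consensus[0, 1:4] = consensus[1:4, 0] = 0.1
    consensus[0, 4:] = consensus[4:, 0] = 0.9
    res = _consensus_result(consensus, [1] * 4 + [2] * 4)
    core, dropped = silhouette_filter(res)
    assert "s0" in dropped


# --- SAM --------------------------------------------------------------------


def test_sam_null_controls_selection():
    rng = np.random.default_rng(8)
    m = ExpressionMatrix([f"g{i}" for i in range(300)],
                         [f"s{j}" for j in range(40)],
                         rng.normal(0, 1, size=(300, 40)))
    labels = pd.Series(["A"] * 20 + ["B"] * 20, index=m.sample_ids)
    table = sam_multiclass(m, labels, fdr_threshold=0.05, n_permutations=50, seed=8)
    assert table["selected"].sum() <= 0.05 * 300 + 3


def test_sam_power_on_planted_markers(small_model, small_cohort):
    matrix, labels, _ = small_cohort
    table = sam_multiclass(matrix, labels, fdr_threshold=0.005,
                           n_permutations=50, seed=1)
    planted = {g for genes in small_model.marker_genes().values() for g in genes}
    selected = set(table.index[table["selected"]])
    assert planted <= selected
    assert table.loc[sorted(planted), "q_value"].max() <= 0.005


def test_sam_constant_gene_never_selected():
    rng = np.random.default_rng(9)
    values = rng.normal(0, 1, size=(20, 30))
    values[0, :] = 5.0
    m = ExpressionMatrix([f"g{i}" for i in range(20)], [f"s{j}" for j in range(30)], values)
    labels = pd.Series(["A"] * 15 + ["B"] * 15, index=m.sample_ids)
    table = sam_multiclass(m, labels, n_permutations=30, seed=0)
    assert table.loc["g0", "statistic"] == pytest.approx(0.0)
    assert not table.loc["g0", "selected"]


def test_sam_requires_enough_permutations(small_cohort):
    matrix, labels, _ = small_cohort
    with pytest.raises(ValidationError, match="n_permutations"):
        sam_multiclass(matrix, labels, n_permutations=10)


# --- PAM --------------------------------------------------------------------


def _toy_separable():
    rng = np.random.default_rng(10)
    n = 20
    values = rng.normal(0, 0.3, size=(30, 2 * n))
    values[:10, :n] += 3.0
    values[10:20, n:] += 3.0
    m = ExpressionMatrix([f"g{i}" for i in range(30)],
                         [f"s{j}" for j in range(2 * n)], values)
    labels = pd.Series(["A"] * n + ["B"] * n, index=m.sample_ids)
    return m, labels


def test_pam_separable_reaches_zero_cv_error():
    m, labels = _toy_separable()
    model = pam_train(m, labels)
    assert model.cv_error == 0.0
    assert model.active_genes.sum() >= 20


def test_pam_zero_delta_equals_plain_centroids():
    m, labels = _toy_separable()
    model = pam_train(m, labels, delta_grid=[0.0])
    np.testing.assert_allclose(
        model.shrunken_scores,
        (model.centroids - model.overall_centroid[:, None])
        / (np.array([np.sqrt(1 / 20 - 1 / 40)] * 2)[None, :]
           * (model.pooled_sd + model.s0)[:, None]),
    )


def test_pam_huge_delta_inactivates_all_genes():
    m, labels = _toy_separable()
    model = pam_train(m, labels, delta_grid=[1e6])
    assert model.active_genes.sum() == 0


def test_pam_singleton_class_rejected():
    m, labels = _toy_separable()
    labels = labels.copy()
    labels.iloc[0] = "C"
    with pytest.raises(ValidationError, match="LOOCV"):
        pam_train(m, labels)


# --- stromal filter and non-redundant assignment ----------------------------


def test_stromal_filter_strictness():
    table = pd.Series({"a": 0.6, "b": 0.5, "c": 0.0})
    kept, removed = stromal_filter(["a", "b", "c"], table)
    assert removed == ["a"]  # above 50% is strict
    assert kept == ["b", "c"]


def test_stromal_filter_extreme_thresholds():
    table = pd.Series({"a": 0.9, "b": 0.1, "c": 0.0})
    assert stromal_filter(["a", "b", "c"], table, threshold=1.0)[1] == []
    assert stromal_filter(["a", "b", "c"], table, threshold=0.0)[1] == ["a", "b"]


def test_stromal_filter_missing_gene_kept():
    kept, removed = stromal_filter(["a", "zz"], pd.Series({"a": 0.9}))
    assert kept == ["zz"] and removed == ["a"]


def test_stromal_filter_rejects_bad_fraction():
    with pytest.raises(ValidationError):
        stromal_filter(["a"], pd.Series({"a": 1.2}))


def _pam_with_scores(scores: pd.DataFrame) -> PamModel:
    g = len(scores)
    return PamModel(
        gene_ids=list(scores.index), classes=list(scores.columns),
        shrunken_scores=scores.to_numpy(float), centroids=np.zeros((g, scores.shape[1])),
        overall_centroid=np.zeros(g), pooled_sd=np.ones(g), s0=0.1,
        threshold=0.0, cv_error=0.0,
    )


def test_assign_nonredundant_rules():
    scores = pd.DataFrame(
        {"A": [0.5, 0.5, 0.5, -0.1], "B": [0.0, 0.1, 0.4, 0.3]},
        index=["only_a", "clear_a", "ambiguous", "only_b"],
    )
    sig = assign_nonredundant(_pam_with_scores(scores), gap=0.2)
    assert sig.genes_by_class["A"] == ["only_a", "clear_a"]
    assert sig.genes_by_class["B"] == ["only_b"]
    assert "ambiguous" not in sig.all_genes


def test_assign_nonredundant_empty_class_errors():
    scores = pd.DataFrame({"A": [0.5], "B": [-0.5]}, index=["g"])
    with pytest.raises(ValidationError, match="0 genes"):
        assign_nonredundant(_pam_with_scores(scores))


# --- cascade bookkeeping ----------------------------------------------------


def test_cascade_arithmetic():
    report = filter_cascade_report(903, 102, 84)
    assert report["pre_redundancy_pool"] == 717
    report = filter_cascade_report(717, 0, 0, 152)
    assert report["final_classifier_size"] == 565
    assert filter_cascade_report(100)["final_classifier_size"] == 100


def test_cascade_negative_intermediate_errors():
    with pytest.raises(ValidationError):
        filter_cascade_report(10, 20, 0)
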