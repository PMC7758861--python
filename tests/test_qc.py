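import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from formhaem.errors import InputError
from formhaem.qc import (
    DoubletConfig,
    QcThresholds,
    normalize_total,
    qc_filter,
    remove_top_doublets,
    run_qc_stage,
    simulate_and_score_doublets,
)


def _adata_from_counts(counts, sample="s1", gene_prefix="g", mito_idx=()):
    counts = sp.csr_matrix(np.asarray(counts, dtype=float))
    n, m = counts.shape
    var = pd.DataFrame(index=[f"{gene_prefix}{j}" for j in range(m)])
    var["mito"] = [j in set(mito_idx) for j in range(m)]
    obs = pd.DataFrame(index=[f"c{i:04d}" for i in range(n)])
    obs["sample"] = sample
    adata = ad.AnnData(X=counts.copy(), obs=obs, var=var)
    adata.layers["counts"] = counts
    return adata


# ---------------------------------------------------------------- doublets


def test_doublet_scores_rank_planted_doublets_higher(hemato_sample):
    adata, truth, _ = hemato_sample
    scores = simulate_and_score_doublets(adata, DoubletConfig(seed=0))
    is_doublet = truth.cells["is_doublet"].to_numpy()
    assert scores[is_doublet].mean() > 1.5 * scores[~is_doublet].mean()


def test_doublet_removal_count_is_ceiling_of_fraction():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5.0, size=(2000, 60))
    adata = _adata_from_counts(counts)
    scores = rng.random(2000)
    kept, report = remove_top_doublets(adata, scores, QcThresholds())
    # ceil(0.045 * 2000) = 90
    assert adata.n_obs - kept.n_obs == 90
    assert report.per_cell["removed_as_doublet"].sum() == 90


def test_doublet_removal_is_per_sample():
    rng = np.random.default_rng(1)
    counts = rng.poisson(5.0, size=(300, 40))
    adata = _adata_from_counts(counts)
    adata.obs["sample"] = ["a"] * 100 + ["b"] * 200
    scores = rng.random(300)
    kept, report = remove_top_doublets(adata, scores, QcThresholds())
    removed = report.per_cell["removed_as_doublet"]
    assert removed[adata.obs["sample"] == "a"].sum() == math.ceil(0.045 * 100)
    assert removed[adata.obs["sample"] == "b"].sum() == math.ceil(0.045 * 200)


def test_doublet_removal_takes_exactly_the_top_scores():
    rng = np.random.default_rng(2)
    counts = rng.poisson(5.0, size=(100, 30))
    adata = _adata_from_counts(counts)
    scores = np.arange(100, dtype=float)  # strictly increasing, no ties
    kept, report = remove_top_doublets(adata, scores, QcThresholds())
    n_remove = math.ceil(0.045 * 100)
    removed_cells = set(report.per_cell.index[report.per_cell["removed_as_doublet"]])
    expected = {f"c{i:04d}" for i in range(100 - n_remove, 100)}
    assert removed_cells == expected


# ---------------------------------------------------------------- rules


def test_mito_rule_is_strictly_greater_than():
    # 3 genes, gene 2 mitochondrial; cell totals 100 with mito 10 / 11
    counts = np.array([[45, 45, 10], [44, 45, 11], [90, 10, 0]])
    adata = _adata_from_counts(counts, mito_idx=(2,))
    thresholds = QcThresholds(min_genes=1, umi_sd_limit=100.0)
    kept, report = qc_filter(adata, thresholds)
    assert report.per_cell["fail_mito"].tolist() == [False, True, False]
    assert kept.n_obs == 2


def test_gene_count_rule_boundary():
    # min_genes=3: a cell expressing exactly 3 genes is kept, 2 is removed
    counts = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [1, 1, 1, 1]])
    adata = _adata_from_counts(counts)
    thresholds = QcThresholds(min_genes=3, umi_sd_limit=100.0)
    kept, report = qc_filter(adata, thresholds)
    assert report.per_cell["fail_genes"].tolist() == [False, True, False]


def test_umi_outlier_rule_uses_per_sample_sd():
    # sample a: tight totals plus one huge outlier; sample b: all equal
    rows = [[10] * 5] * 20 + [[200] * 5] + [[30] * 5] * 10
    adata = _adata_from_counts(np.array(rows))
    adata.obs["sample"] = ["a"] * 21 + ["b"] * 10
    thresholds = QcThresholds(min_genes=1, umi_sd_limit=3.0)
    kept, report = qc_filter(adata, thresholds)
    fail = report.per_cell["fail_umi_sd"]
    assert fail.iloc[20]  # the planted outlier
    assert fail.iloc[:20].sum() == 0 and fail.iloc[21:].sum() == 0


def test_qc_filter_agrees_with_brute_force(hemato_sample):
    """Vectorized rules match a literal per-cell reimplementation."""
    adata, _, _ = hemato_sample
    sub = adata[:200, :100].copy()
    thresholds = QcThresholds(max_mito_fraction=0.10, min_genes=40, umi_sd_limit=3.0)
    _, report = qc_filter(sub, thresholds)

    counts = np.asarray(sub.layers["counts"].todense())
    mito = sub.var["mito"].to_numpy(dtype=bool)
    totals = counts.sum(axis=1)
    mean, sd = totals.mean(), totals.std(ddof=0)
    for i in range(sub.n_obs):
        total = counts[i].sum()
        expect_mito = (counts[i][mito].sum() / total if total else 0.0) > 0.10
        expect_genes = (counts[i] > 0).sum() < 40
        expect_umi = abs(total - mean) > 3.0 * sd if sd > 0 else False
        row = report.per_cell.iloc[i]
        assert row["fail_mito"] == expect_mito
        assert row["fail_genes"] == expect_genes
        assert row["fail_umi_sd"] == expect_umi


def test_stricter_thresholds_never_keep_more_cells(hemato_sample):
    adata, _, _ = hemato_sample
    loose, _ = qc_filter(adata, QcThresholds(max_mito_fraction=0.2, min_genes=100))
    tight, _ = qc_filter(adata, QcThresholds(max_mito_fraction=0.05, min_genes=400))
    assert tight.n_obs <= loose.n_obs
    assert set(tight.obs_names) <= set(loose.obs_names)


def test_low_quality_cells_are_caught(hemato_sample):
    """At least 90% of the planted high-mito low-complexity cells fail QC."""
    adata, truth, _ = hemato_sample
    _, report = qc_filter(adata, QcThresholds(max_mito_fraction=0.10, min_genes=400))
    failed = report.per_cell[["fail_mito", "fail_genes", "fail_umi_sd"]].any(axis=1)
    lowq = truth.cells["is_lowquality"].to_numpy()
    assert failed.to_numpy()[lowq].mean() >= 0.90


# ---------------------------------------------------------------- normalization


def test_normalization_equalizes_totals_and_keeps_counts():
    counts = np.array([[4, 0, 4], [1, 1, 0], [10, 10, 20]])
    adata = _adata_from_counts(counts)
    out = normalize_total(adata, target_sum=100.0)
    totals = np.asarray(out.X.sum(axis=1)).ravel()
    np.testing.assert_allclose(totals, 100.0)
    np.testing.assert_array_equal(np.asarray(out.layers["counts"].todense()), counts)


def test_normalization_default_target_is_median():
    counts = np.diag([2.0, 10.0, 50.0])
    adata = _adata_from_counts(counts)
    out = normalize_total(adata)
    assert out.uns["normalization_target_sum"] == 10.0


def test_normalization_drops_zero_total_cells():
    counts = np.array([[1, 2], [0, 0], [3, 4]])
    adata = _adata_from_counts(counts)
    out = normalize_total(adata, target_sum=10.0)
    assert out.n_obs == 2


# ---------------------------------------------------------------- stage


def test_run_qc_stage_reports_every_input_cell(hemato_sample):
    adata, truth, _ = hemato_sample
    clean, report = run_qc_stage(
        adata,
        QcThresholds(max_mito_fraction=0.10, min_genes=400),
        DoubletConfig(seed=0),
    )
    assert len(report.per_cell) == adata.n_obs
    # conservation: retained + removed across samples equals the input
    assert report.per_sample["total"].sum() == adata.n_obs
    assert clean.n_obs == report.per_sample["retained"].sum()
    assert clean.n_obs < adata.n_obs


def test_run_qc_stage_is_deterministic(hemato_sample):
    adata, _, _ = hemato_sample
    t = QcThresholds(max_mito_fraction=0.10, min_genes=400)
    c1, r1 = run_qc_stage(adata, t, DoubletConfig(seed=4))
    c2, r2 = run_qc_stage(adata, t, DoubletConfig(seed=4))
    assert list(c1.obs_names) == list(c2.obs_names)
    pd.testing.assert_frame_equal(r1.per_cell, r2.per_cell)


def test_invalid_inputs_raise():
    with pytest.raises(InputError):
        QcThresholds(max_mito_fraction=0.0)
    with pytest.raises(InputError):
        QcThresholds(doublet_removal_fraction=1.5)
    with pytest.raises(InputError):
        DoubletConfig(k_neighbors=0)
    adata = _adata_from_counts(np.ones((5, 4)))
    with pytest.raises(InputError):
        simulate_and_score_doublets(adata, DoubletConfig(k_neighbors=30))
    with pytest.raises(InputError):
        remove_top_doublets(adata, np.zeros(3), QcThresholds())
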