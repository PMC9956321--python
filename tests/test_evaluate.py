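"""Cross-validated evaluation: metrics, strategies, overlap report."""

import numpy as np
import pandas as pd
import pytest

from outlierboot import (
    BootstrapConfig,
    EvalConfig,
    ExpressionDataset,
    SimConfig,
    StrategySpec,
    brier_score,
    confusion_metrics,
    cv_evaluate,
    de_overlap_report,
    run_strategies,
    simulate_dataset,
)


# --------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------- #
def test_brier_closed_forms():
    y = np.array(["n", "p", "p", "n"])
    assert brier_score(y, np.array([0.0, 1.0, 1.0, 0.0])) == 0.0
    assert brier_score(y, np.full(4, 0.5)) == 0.25


def test_brier_elementwise_oracle(rng):
    y = rng.choice(["a", "b"], size=50)
    p = rng.uniform(size=50)
    ref = np.mean([( (1.0 if yi == "b" else 0.0) - pi) ** 2 for yi, pi in zip(y, p)])
    assert brier_score(y, p) == pytest.approx(ref, abs=1e-12)


def test_brier_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        brier_score(["a", "b"], [0.5, 1.2])


def test_confusion_metrics_hand_table():
    # TP=3, FP=1, TN=4, FN=2
    y_true = ["p"] * 5 + ["n"] * 5
    y_pred = ["p", "p", "p", "n", "n", "p", "n", "n", "n", "n"]
    m = confusion_metrics(y_true, y_pred, positive="p")
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.8)
    assert m["ppv"] == pytest.approx(0.75)
    assert m["npv"] == pytest.approx(2 / 3)


def test_confusion_metrics_all_correct_and_complement():
    y = ["p", "n", "p", "n"]
    perfect = confusion_metrics(y, y, "p")
    assert all(perfect[m] == 1.0 for m in perfect)
    flipped = ["n", "p", "n", "p"]
    m = confusion_metrics(y, flipped, "p")
    assert m["accuracy"] == 0.0 and m["sensitivity"] == 0.0 and m["specificity"] == 0.0


def test_confusion_metrics_undefined_ratio_is_nan():
    m = confusion_metrics(["n", "n"], ["n", "n"], positive="p")
    assert np.isnan(m["sensitivity"]) and np.isnan(m["ppv"])
    assert m["specificity"] == 1.0


def test_confusion_metrics_accuracy_identity(rng):
    y = rng.choice(["p", "n"], size=40)
    yhat = rng.choice(["p", "n"], size=40)
    m = confusion_metrics(y, yhat, "p")
    n_pos, n_neg = int((y == "p").sum()), int((y == "n").sum())
    acc = (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / 40
    assert m["accuracy"] == pytest.approx(acc)


# --------------------------------------------------------------------- #
# cross-validation
# --------------------------------------------------------------------- #
def _two_cluster_dataset(rng, n_per=15, d=60, gap=10.0):
    X = rng.normal(size=(d, 2 * n_per))
    X[:, n_per:] += gap
    ids = [f"s{i}" for i in range(2 * n_per)]
    return ExpressionDataset(
        expression=pd.DataFrame(X, columns=ids),
        groups=pd.Series(["g1"] * n_per + ["g2"] * n_per, index=ids),
    )


@pytest.mark.parametrize("classifier", ["svm", "rf", "lda"])
def test_perfectly_separable_clusters(classifier, rng):
    ds = _two_cluster_dataset(rng)
    cfg = EvalConfig(
        classifier=classifier, n_cv_runs=5, gene_grid=(10, 20),
        rf_n_trees=50, seed=0,
    )
    perf = cv_evaluate(ds, cfg)
    assert np.allclose(perf["accuracy_mean"], 1.0)
    assert (perf["brier_mean"] < 0.1).all()


def test_permutation_null_accuracy_near_chance(rng):
    d, n = 50, 200
    X = rng.normal(size=(d, n))
    ids = [f"s{i}" for i in range(n)]
    labels = rng.permutation(["g1"] * (n // 2) + ["g2"] * (n // 2))
    ds = ExpressionDataset(
        expression=pd.DataFrame(X, columns=ids),
        groups=pd.Series(labels, index=ids),
    )
    perf = cv_evaluate(ds, EvalConfig(classifier="lda", n_cv_runs=20, gene_grid=(10,), seed=1))
    assert abs(perf["accuracy_mean"].iloc[0] - 0.5) < 0.1


def test_cv_reproducible_with_same_seed(small_sim):
    cfg = EvalConfig(classifier="lda", n_cv_runs=4, gene_grid=(10, 30), seed=5)
    a = cv_evaluate(small_sim, cfg)
    b = cv_evaluate(small_sim, cfg)
    pd.testing.assert_frame_equal(a, b)


def test_lda_regularized_when_features_exceed_training(rng):
    ds = _two_cluster_dataset(rng, n_per=8, d=120, gap=2.0)
    cfg = EvalConfig(classifier="lda", n_cv_runs=3, gene_grid=(100,), seed=2)
    perf = cv_evaluate(ds, cfg)
    assert perf["brier_mean"].between(0, 1).all()
    assert perf["accuracy_mean"].between(0, 1).all()


def test_cv_requires_enough_samples(small_sim):
    tiny = small_sim.subset_samples(small_sim.sample_ids[:5])
    with pytest.raises(ValueError):
        cv_evaluate(tiny, EvalConfig(n_cv_runs=2))


def test_four_group_reports_accuracy_and_brier_only():
    ds = simulate_dataset(
        SimConfig(n_transcripts=120, n_groups=4, samples_per_group=8,
                  outliers_per_group=0, n_de_transcripts=20,
                  n_outlier_de_transcripts=5, seed=4)
    )
    perf = cv_evaluate(ds, EvalConfig(classifier="lda", n_cv_runs=3, gene_grid=(10,), seed=0))
    assert "accuracy_mean" in perf and "brier_mean" in perf
    assert "sensitivity_mean" not in perf
    assert perf["brier_mean"].between(0, 2).all()


# --------------------------------------------------------------------- #
# strategies
# --------------------------------------------------------------------- #
def test_strategy_b_removes_planted_outliers(small_sim):
    cfg = EvalConfig(classifier="lda", n_cv_runs=3, gene_grid=(10,), seed=3)
    perf = run_strategies(small_sim, ["A", "B"], eval_cfg=cfg)
    assert set(perf["strategy"]) == {"A", "B"}


def test_strategy_b_requires_ground_truth(rng):
    ds = _two_cluster_dataset(rng)
    with pytest.raises(ValueError):
        run_strategies(ds, ["B"], eval_cfg=EvalConfig(n_cv_runs=2, gene_grid=(10,)))


def test_removing_a_whole_group_errors(small_sim):
    g1 = small_sim.sample_ids[small_sim.groups == "group1"].tolist()
    spec = StrategySpec("C", significant_outlier_ids=g1)
    with pytest.raises(ValueError):
        run_strategies(
            small_sim, [spec], eval_cfg=EvalConfig(n_cv_runs=2, gene_grid=(10,))
        )


def test_empty_strategy_list_errors(small_sim):
    with pytest.raises(ValueError):
        run_strategies(small_sim, [])


# --------------------------------------------------------------------- #
# overlap report
# --------------------------------------------------------------------- #
def test_overlap_identical_strategies_is_total(small_sim):
    cfg = EvalConfig(n_cv_runs=4, seed=8)
    rep = de_overlap_report(small_sim, ("A", "A"), cfg, top_n=30)
    assert rep["overlap_count"] == 30
    assert rep["overlap_percent"] == 100.0


def test_overlap_frequencies_bounded(small_sim):
    cfg = EvalConfig(n_cv_runs=5, seed=9)
    spec_b = StrategySpec("B")
    rep = de_overlap_report(small_sim, ("A", spec_b), cfg, top_n=25)
    freq = rep["frequencies"]
    assert freq[["A", "B"]].to_numpy().min() >= 0
    assert freq[["A", "B"]].to_numpy().max() <= cfg.n_cv_runs
    assert 0 <= rep["overlap_count"] <= 25
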