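"""Bootstrap outlier probabilities and exact binomial inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from outlierboot import (
    BootstrapConfig,
    BootstrapOutlierProbability,
    ExpressionDataset,
    SimConfig,
    binom_pvalue_greater,
    bootstrap_outlier_probabilities,
    clopper_pearson_lower,
    significant_outliers,
    simulate_dataset,
)


# --------------------------------------------------------------------- #
# exact binomial machinery
# --------------------------------------------------------------------- #
def test_pvalue_edge_cases():
    assert binom_pvalue_greater(0, 10) == 1.0
    assert binom_pvalue_greater(10, 10) == pytest.approx(0.5**10)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(n=st.integers(1, 200), frac=st.floats(0, 1))
def test_pvalue_matches_scipy_binomtest(n, frac):
    k = int(round(frac * n))
    mine = binom_pvalue_greater(k, n)
    ref = sps.binomtest(k, n, 0.5, alternative="greater").pvalue
    assert mine == pytest.approx(ref, abs=1e-12)


def test_pvalue_monotone_in_detections():
    ps = [binom_pvalue_greater(k, 80) for k in range(81)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_ci_lower_edge_cases():
    assert clopper_pearson_lower(0, 20) == 0.0
    assert clopper_pearson_lower(68, 68) == pytest.approx(0.05 ** (1 / 68))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(n=st.integers(1, 150), frac=st.floats(0, 1))
def test_ci_lower_matches_statsmodels(n, frac):
    from statsmodels.stats.proportion import proportion_confint

    k = int(round(frac * n))
    mine = clopper_pearson_lower(k, n, alpha=0.05)
    # two-sided exact interval at level 0.10 shares our one-sided 5% lower bound
    ref = proportion_confint(k, n, alpha=0.10, method="beta")[0]
    assert mine == pytest.approx(ref, abs=1e-10)


@pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
def test_invalid_counts_rejected(k, n):
    with pytest.raises(ValueError):
        binom_pvalue_greater(k, n)
    with pytest.raises(ValueError):
        clopper_pearson_lower(k, n)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "occurrences",
            "detections",
            "outlier_probability",
            "ci_lower",
            "p_value",
            "significant",
        ],
    )


def test_significant_outliers_selection_and_order():
    rows = []
    for sid, (k, n) in {"a": (68, 68), "b": (0, 60), "c": (50, 60)}.items():
        rows.append(
            (sid, n, k, k / n, clopper_pearson_lower(k, n),
             binom_pvalue_greater(k, n), binom_pvalue_greater(k, n) < 0.05)
        )
    tab = _table(rows)
    assert significant_outliers(tab) == ["a", "c"]
    # all-zero detections: nothing significant
    zero = _table([("x", 50, 0, 0.0, 0.0, 1.0, False)])
    assert significant_outliers(zero) == []


def test_lower_alpha_never_enlarges_selection():
    rows = [
        (f"s{k}", 70, k, k / 70, clopper_pearson_lower(k, 70),
         binom_pvalue_greater(k, 70), False)
        for k in range(0, 71, 5)
    ]
    tab = _table(rows)
    sets = [set(significant_outliers(tab, alpha)) for alpha in (0.1, 0.05, 0.01)]
    assert sets[0] >= sets[1] >= sets[2]


# --------------------------------------------------------------------- #
# the bootstrap loop
# --------------------------------------------------------------------- #
def test_bootstrap_table_invariants_and_determinism(small_sim):
    cfg = BootstrapConfig(n_runs=20, seed=4)
    tab = bootstrap_outlier_probabilities(small_sim, cfg)
    tab2 = bootstrap_outlier_probabilities(small_sim, cfg)
    pd.testing.assert_frame_equal(tab, tab2)
    drawn = tab[tab.occurrences > 0]
    assert ((drawn.detections >= 0) & (drawn.detections <= drawn.occurrences)).all()
    assert (drawn.occurrences <= cfg.n_runs).all()
    assert drawn.outlier_probability.between(0, 1).all()
    assert drawn.ci_lower.between(0, 1).all()
    assert (drawn.significant == (drawn.p_value < cfg.alpha)).all()


def test_mean_occurrence_near_bootstrap_inclusion_rate(small_sim):
    runs = 60
    tab = bootstrap_outlier_probabilities(small_sim, BootstrapConfig(n_runs=runs, seed=2))
    N = small_sim.n_samples
    expected = runs * (1.0 - (1.0 - 1.0 / N) ** N)
    assert tab.occurrences.mean() == pytest.approx(expected, rel=0.05)


def test_displaced_sample_gets_high_probability():
    """A sample shifted by +50 noise sd on 100 transcripts must come out
    with outlier probability > 0.9 and a significant test."""
    n_seeds = 10
    hits = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        d, n = 150, 30
        X = rng.normal(8.0, 1.0, size=(d, 2 * n))
        X[:100, 5] += 50.0
        ids = [f"s{i}" for i in range(2 * n)]
        ds = ExpressionDataset(
            expression=pd.DataFrame(X, columns=ids),
            groups=pd.Series(["g1"] * n + ["g2"] * n, index=ids),
        )
        tab = bootstrap_outlier_probabilities(ds, BootstrapConfig(n_runs=100, seed=seed))
        row = tab.set_index("sample_id").loc["s5"]
        if row.outlier_probability > 0.9 and row.significant:
            hits += 1
    assert hits == n_seeds


def test_single_run_matches_hand_trace():
    """With one bootstrap run the table reduces to a single detector pass."""
    from sklearn.decomposition import PCA

    from outlierboot import detect_outliers_bagplot

    ds = simulate_dataset(
        SimConfig(n_transcripts=60, samples_per_group=10, outliers_per_group=2,
                  n_de_transcripts=10, n_outlier_de_transcripts=8, seed=6)
    )
    cfg = BootstrapConfig(n_runs=1, seed=99)
    tab = bootstrap_outlier_probabilities(ds, cfg).set_index("sample_id")

    rng = np.random.default_rng(99)
    N = ds.n_samples
    idx = rng.integers(0, N, size=N)
    X = ds.values_samples_by_transcripts()
    scores = PCA(n_components=2).fit_transform(X[idx])
    gb = ds.groups.to_numpy()[idx]
    expected_flags = set()
    for g in sorted(set(gb)):
        mask = gb == g
        flags = detect_outliers_bagplot(scores[mask], factor=2.0).is_outlier
        expected_flags.update(np.asarray(idx)[mask][flags].tolist())
    present = set(np.unique(idx))
    for i, sid in enumerate(ds.sample_ids):
        row = tab.loc[sid]
        assert row.occurrences == (1 if i in present else 0)
        assert row.detections == (1 if i in expected_flags else 0)


def test_null_calibration_few_significant_flags():
    """Outlier-free spherical Gaussian data: well under 5% of samples
    should be declared significant outliers."""
    frac = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        X = rng.normal(size=(50, 40))
        ids = [f"s{i}" for i in range(40)]
        ds = ExpressionDataset(
            expression=pd.DataFrame(X, columns=ids),
            groups=pd.Series(["g1"] * 20 + ["g2"] * 20, index=ids),
        )
        tab = bootstrap_outlier_probabilities(ds, BootstrapConfig(n_runs=30, seed=seed))
        frac.append(tab.significant.mean())
    assert np.mean(frac) < 0.05


def test_group_size_validation(small_sim):
    ids = small_sim.sample_ids[:6].tolist() + small_sim.sample_ids[-2:].tolist()
    tiny = small_sim.subset_samples(ids)
    with pytest.raises(ValueError):
        bootstrap_outlier_probabilities(tiny, BootstrapConfig(n_runs=2, seed=0))


def test_estimator_interface(small_sim):
    X = small_sim.values_samples_by_transcripts()
    y = small_sim.groups.to_numpy()
    est = BootstrapOutlierProbability(n_runs=15, seed=3)
    flags = est.fit_predict(X, y)
    assert flags.shape == (X.shape[0],)
    assert set(np.unique(flags)) <= {-1, 1}
    assert len(est.outlier_table_) == X.shape[0]
    # sklearn param plumbing
    assert est.get_params()["n_runs"] == 15
    est.set_params(n_runs=5)
    assert est.n_runs == 5
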