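"""Bootstrap estimation of per-sample outlier probabilities.

A single pass of any outlier detector answers only "is this sample flagged
in this dataset"; the answer can flip when the sample composition changes.
The bootstrap procedure quantifies that instability: the dataset is
resampled with replacement many times (100 by default); in every resampled
dataset a classical PCA is computed on all groups jointly, the component
scores are split by study group, and a 2-D outlier detector (bagplot or
PCA-Grid) is applied to each group's point cloud.  For every sample the
procedure counts

* ``n``  — the number of bootstrap runs that contained the sample at least
  once (its *occurrences*), and
* ``k``  — the number of those runs in which it was flagged (*detections*),

and reports the outlier probability ``k/n`` together with an exact
one-sided binomial test of H0: p <= 0.5 and the matching one-sided 95%
Clopper-Pearson lower confidence bound.  A sample is declared a
*significant outlier* when the p-value falls below the significance level
(0.05 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .bagplot import detect_outliers_bagplot
from .dataset import ExpressionDataset
from .pcagrid import detect_outliers_pcagrid

__all__ = [
    "BootstrapConfig",
    "binom_pvalue_greater",
    "clopper_pearson_lower",
    "significant_outliers",
    "bootstrap_outlier_probabilities",
    "BootstrapOutlierProbability",
]

logger = logging.getLogger(__name__)

#: column layout of the outlier table
TABLE_COLUMNS = [
    "sample_id",
    "occurrences",
    "detections",
    "outlier_probability",
    "ci_lower",
    "p_value",
    "significant",
]


# --------------------------------------------------------------------- #
# exact binomial inference
# --------------------------------------------------------------------- #
def _check_counts(k: int, n: int) -> tuple[int, int]:
    k, n = int(k), int(n)
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    return k, n


def binom_pvalue_greater(k: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided upper tail P(X >= k) for X ~ Binomial(n, p0).

    Computed by direct summation of the binomial probability mass from
    ``k`` to ``n``.
    """
    k, n = _check_counts(k, n)
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.binom.pmf(np.arange(k, n + 1), n, p0).sum()))


def clopper_pearson_lower(k: int, n: int, alpha: float = 0.05) -> float:
    """One-sided exact (Clopper-Pearson) lower confidence bound.

    The bound is the ``alpha`` quantile of a Beta(k, n - k + 1)
    distribution; 0 when ``k = 0`` and ``alpha**(1/n)`` when ``k = n``.
    The reported interval is ``[lower, 1.0]``.
    """
    k, n = _check_counts(k, n)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k == 0:
        return 0.0
    return float(stats.beta.ppf(alpha, k, n - k + 1))


def significant_outliers(table: pd.DataFrame, alpha: float = 0.05) -> list:
    """Sample ids whose binomial p-value is below ``alpha``.

    Sorted by descending outlier probability, ties by sample id.  Samples
    never drawn in any run (``occurrences = 0``) are excluded.
    """
    tab = table[(table["occurrences"] > 0) & (table["p_value"] < alpha)]
    tab = tab.sort_values(
        ["outlier_probability", "sample_id"], ascending=[False, True]
    )
    return tab["sample_id"].tolist()


# --------------------------------------------------------------------- #
# the bootstrap loop
# --------------------------------------------------------------------- #
@dataclass
class BootstrapConfig:
    """Knobs of the bootstrap outlier-probability procedure.

    ``n_runs`` bootstrap datasets are drawn (100 by default); ``detector``
    is ``"bagplot"`` (fence factor ``factor``) or ``"pcagrid"``;
    ``n_pcs`` classical components are computed per run (2 by default —
    the bagplot detector requires exactly 2); ``alpha`` is the level of the
    binomial test and of the one-sided confidence bound.
    """

    n_runs: int = 100
    detector: str = "bagplot"
    factor: float = 2.0
    alpha: float = 0.05
    n_pcs: int = 2
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.detector not in ("bagplot", "pcagrid"):
            raise ValueError("detector must be 'bagplot' or 'pcagrid'")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.detector == "bagplot" and self.n_pcs != 2:
            raise ValueError("the bagplot detector requires n_pcs = 2")


_DETECTOR_MIN_SAMPLES = 4  # below this a group is skipped for the run


def _detect_group(scores: np.ndarray, cfg: BootstrapConfig) -> np.ndarray:
    """Boolean flags for one group's bootstrap score cloud."""
    if cfg.detector == "bagplot":
        return detect_outliers_bagplot(scores[:, :2], factor=cfg.factor).is_outlier
    k = min(cfg.n_pcs, scores.shape[0] - 1, scores.shape[1])
    res = detect_outliers_pcagrid(scores, k=k)
    return res.is_outlier


def bootstrap_outlier_probabilities(
    ds: ExpressionDataset, cfg: BootstrapConfig | None = None, **kwargs
) -> pd.DataFrame:
    """Estimate the outlier probability of every sample of ``ds``.

    Returns a table with one row per sample: occurrences ``n``, detections
    ``k``, outlier probability ``k/n``, one-sided Clopper-Pearson lower
    bound, exact binomial p-value for H0: p <= 0.5, and the significance
    flag at ``cfg.alpha``.  A sample that was never drawn (possible at
    small ``n_runs``) is reported with ``n = 0`` and missing probability,
    bound and p-value, and is never significant.

    Resampling draws the full dataset size with replacement, unstratified
    by default; duplicated copies of a sample enter the detector as
    coincident points, but the sample counts only once per run for both
    occurrence and detection.
    """
    if cfg is None:
        cfg = BootstrapConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a BootstrapConfig or keyword arguments")

    groups = ds.groups
    levels = ds.group_levels()
    if len(levels) < 2:
        raise ValueError("need at least 2 study groups")
    sizes = groups.value_counts()
    if (sizes < 4).any():
        raise ValueError("every group needs at least 4 samples")

    X = ds.values_samples_by_transcripts()
    gcodes = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    N = X.shape[0]
    rng = np.random.default_rng(cfg.seed)

    occurrences = np.zeros(N, dtype=int)
    detections = np.zeros(N, dtype=int)

    for run in range(cfg.n_runs):
        if cfg.stratified:
            idx = np.concatenate(
                [
                    rng.choice(np.flatnonzero(gcodes == g), size=(gcodes == g).sum(), replace=True)
                    for g in range(len(levels))
                ]
            )
        else:
            idx = rng.integers(0, N, size=N)
        present = np.unique(idx)
        occurrences[present] += 1

        n_pcs = min(cfg.n_pcs, len(idx) - 1, X.shape[1])
        scores = PCA(n_components=n_pcs).fit_transform(X[idx])

        flagged_runwise: set[int] = set()
        for g in range(len(levels)):
            mask = gcodes[idx] == g
            if mask.sum() < _DETECTOR_MIN_SAMPLES:
                logger.warning(
                    "run %d: group %r has %d bootstrap samples; skipped",
                    run,
                    levels[g],
                    int(mask.sum()),
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flags = _detect_group(scores[mask], cfg)
            flagged_runwise.update(idx[mask][flags].tolist())
        for i in flagged_runwise:
            detections[i] += 1

    rows = []
    for i, sid in enumerate(ds.sample_ids):
        n, k = int(occurrences[i]), int(detections[i])
        if n == 0:
            rows.append((sid, 0, 0, np.nan, np.nan, np.nan, False))
            continue
        p = k / n
        rows.append(
            (
                sid,
                n,
                k,
                p,
                clopper_pearson_lower(k, n, cfg.alpha),
                binom_pvalue_greater(k, n, 0.5),
                binom_pvalue_greater(k, n, 0.5) < cfg.alpha,
            )
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


class BootstrapOutlierProbability(BaseEstimator):
    """Estimator interface to the bootstrap outlier-probability procedure.

    ``fit(X, y)`` takes a samples-by-transcripts matrix and group labels
    ``y``; fitted attributes are ``outlier_table_`` (the per-sample table)
    and ``significant_outliers_`` (positional indices of significant
    samples).  ``fit_predict`` returns -1/+1 flags in the sklearn outlier
    convention.
    """

    def __init__(
        self,
        n_runs: int = 100,
        detector: str = "bagplot",
        factor: float = 2.0,
        alpha: float = 0.05,
        n_pcs: int = 2,
        stratified: bool = False,
        seed: int = 0,
    ):
        self.n_runs = n_runs
        self.detector = detector
        self.factor = factor
        self.alpha = alpha
        self.n_pcs = n_pcs
        self.stratified = stratified
        self.seed = seed

    def _config(self) -> BootstrapConfig:
        return BootstrapConfig(
            n_runs=self.n_runs,
            detector=self.detector,
            factor=self.factor,
            alpha=self.alpha,
            n_pcs=self.n_pcs,
            stratified=self.stratified,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be samples x features with one label per row")
        sample_ids = pd.RangeIndex(X.shape[0])
        ds = ExpressionDataset(
            expression=pd.DataFrame(X.T, columns=sample_ids),
            groups=pd.Series(y, index=sample_ids),
        )
        self.outlier_table_ = bootstrap_outlier_probabilities(ds, self._config())
        self.significant_outliers_ = significant_outliers(
            self.outlier_table_, self.alpha
        )
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y):
        self.fit(X, y)
        check_is_fitted(self, "outlier_table_")
        flags = np.ones(X.shape[0], dtype=int)
        flags[np.asarray(self.significant_outliers_, dtype=int)] = -1
        return flags
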