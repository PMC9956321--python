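"""Cross-validated classifier evaluation under outlier-handling strategies.

Three strategies are compared on the same dataset:

* **A** — keep every sample;
* **B** — remove the known (simulated) outliers, available only when the
  ground truth is recorded;
* **C** — remove the samples that the bootstrap procedure declares
  significant outliers.

For each strategy the classifier (linear SVM, random forest or LDA) is
evaluated by repeated random 2/3-train / 1/3-test splits.  Inside every
split the transcripts are ranked by moderated t on the *training* samples
only, and the classifier is refitted for an increasing number of top
transcripts (10..200 by steps of 10 by default).  Performance per split is
summarized by accuracy, Brier score and — for two classes — sensitivity,
specificity, and positive and negative predictive values, and averaged
(mean +/- standard error) over splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .bootstrap import (
    BootstrapConfig,
    bootstrap_outlier_probabilities,
    significant_outliers,
)
from .dataset import ExpressionDataset
from .features import moderated_t_rank, top_n_transcripts

__all__ = [
    "EvalConfig",
    "StrategySpec",
    "brier_score",
    "confusion_metrics",
    "cv_evaluate",
    "run_strategies",
    "de_overlap_report",
]

logger = logging.getLogger(__name__)

DEFAULT_GENE_GRID = tuple(range(10, 201, 10))

BINARY_METRICS = ("accuracy", "brier", "sensitivity", "specificity", "ppv", "npv")
MULTICLASS_METRICS = ("accuracy", "brier")


@dataclass
class EvalConfig:
    """Cross-validation settings.

    ``classifier`` is ``"svm"`` (linear kernel, cost 10, Platt-scaled
    probabilities), ``"rf"`` (500 trees, sqrt(p) features per split) or
    ``"lda"`` (Ledoit-Wolf-shrunken when the pooled covariance would be
    singular).  ``select_on_full`` ranks transcripts once on the full
    dataset instead of per training split (optimistically biased; off by
    default).
    """

    classifier: str = "svm"
    n_cv_runs: int = 100
    train_fraction: float = 2.0 / 3.0
    gene_grid: tuple = DEFAULT_GENE_GRID
    svm_cost: float = 10.0
    rf_n_trees: int = 500
    stratified: bool = False
    select_on_full: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "rf", "lda"):
            raise ValueError("classifier must be 'svm', 'rf' or 'lda'")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_cv_runs < 1:
            raise ValueError("n_cv_runs must be >= 1")
        self.gene_grid = tuple(int(n) for n in self.gene_grid)
        if any(n < 1 for n in self.gene_grid):
            raise ValueError("gene grid entries must be positive")


@dataclass
class StrategySpec:
    """One outlier-handling strategy: which samples to drop before CV."""

    strategy: str  # "A" | "B" | "C"
    true_outlier_ids: list = field(default_factory=list)  # strategy B
    significant_outlier_ids: list | None = None  # strategy C

    def __post_init__(self) -> None:
        if self.strategy not in ("A", "B", "C"):
            raise ValueError("strategy must be 'A', 'B' or 'C'")


# --------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------- #
def brier_score(y_true, prob, classes=None) -> float:
    """Mean squared difference between class indicators and probabilities.

    Binary form: ``prob`` is the probability of the positive class (taken
    as the last of the sorted labels unless ``classes`` gives the order).
    Multiclass form: ``prob`` is an (n, K) matrix matching ``classes``; the
    score is the mean over samples of the summed squared differences.
    """
    y_true = np.asarray(y_true)
    prob = np.asarray(prob, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if prob.ndim == 1:
        if len(y_true) != len(prob):
            raise ValueError("length mismatch")
        levels = np.array(sorted(np.unique(y_true))) if classes is None else np.asarray(classes)
        positive = levels[-1]
        ind = (y_true == positive).astype(float)
        return float(np.mean((ind - prob) ** 2))
    if classes is None:
        raise ValueError("multiclass Brier needs the class order")
    classes = np.asarray(classes)
    ind = (y_true[:, None] == classes[None, :]).astype(float)
    return float(np.mean(((ind - prob) ** 2).sum(axis=1)))


def confusion_metrics(y_true, y_pred, positive) -> dict:
    """Accuracy, sensitivity, specificity, PPV and NPV for binary labels.

    Ratios with a zero denominator are reported as NaN so that they can be
    excluded from averaging across CV runs.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("labels must be nonempty and of equal length")
    levels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(levels) > 2:
        raise ValueError("confusion_metrics is binary-only")
    tpos = y_true == positive
    ppos = y_pred == positive
    tp = int(np.sum(tpos & ppos))
    fn = int(np.sum(tpos & ~ppos))
    fp = int(np.sum(~tpos & ppos))
    tn = int(np.sum(~tpos & ~ppos))

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    return {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


# --------------------------------------------------------------------- #
# classifiers
# --------------------------------------------------------------------- #
def _make_classifier(cfg: EvalConfig, n_features: int, n_train: int, rng: np.random.Generator):
    if cfg.classifier == "svm":
        return SVC(
            kernel="linear",
            C=cfg.svm_cost,
            probability=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
    if cfg.classifier == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.rf_n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
    if n_features >= n_train:
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    return LinearDiscriminantAnalysis()


# --------------------------------------------------------------------- #
# cross-validation
# --------------------------------------------------------------------- #
def _draw_split(rng, groups: np.ndarray, cfg: EvalConfig):
    N = len(groups)
    n_train = int(round(cfg.train_fraction * N))
    n_train = min(max(n_train, 1), N - 1)
    levels = np.unique(groups)
    for attempt in range(10):
        if cfg.stratified:
            train_idx = []
            for g in levels:
                gi = np.flatnonzero(groups == g)
                k = int(round(cfg.train_fraction * len(gi)))
                k = min(max(k, 1), len(gi) - 1)
                train_idx.append(rng.choice(gi, size=k, replace=False))
            train = np.sort(np.concatenate(train_idx))
        else:
            train = np.sort(rng.choice(N, size=n_train, replace=False))
        test = np.setdiff1d(np.arange(N), train)
        if set(groups[train]) == set(levels) and len(test) > 0:
            return train, test
        logger.warning("redrawing split %d: a class is missing from training", attempt)
    raise RuntimeError("could not draw a training split containing every class")


def cv_evaluate(ds: ExpressionDataset, cfg: EvalConfig) -> pd.DataFrame:
    """Repeated-split cross-validation with incremental feature selection.

    Returns one row per grid value with mean and standard error, across CV
    runs, of every applicable metric.  Binary datasets report all six
    metrics (positive class = lexicographically last group label);
    multi-group datasets report accuracy and multiclass Brier only.
    """
    groups = ds.groups.to_numpy()
    levels = np.array(ds.group_levels())
    counts = pd.Series(groups).value_counts()
    if len(levels) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with >= 3 samples each")
    binary = len(levels) == 2
    metrics = BINARY_METRICS if binary else MULTICLASS_METRICS
    positive = levels[-1] if binary else None
    grid = [n for n in cfg.gene_grid if n <= ds.n_transcripts]
    if not grid:
        raise ValueError("gene grid exceeds the number of transcripts")

    X = ds.values_samples_by_transcripts()
    expr = ds.expression
    rng = np.random.default_rng(cfg.seed)

    full_ranking = None
    if cfg.select_on_full:
        full_ranking = _rank_for_selection(expr, groups, levels)

    per_run: dict[int, dict[str, list]] = {n: {m: [] for m in metrics} for n in grid}
    for _run in range(cfg.n_cv_runs):
        train, test = _draw_split(rng, groups, cfg)
        ranking = full_ranking
        if ranking is None:
            ranking = _rank_for_selection(expr.iloc[:, train], groups[train], levels)
        order = ranking.sort_values("rank").index
        positions = expr.index.get_indexer(order)

        for n in grid:
            feat = positions[:n]
            clf = _make_classifier(cfg, n, len(train), rng)
            with warnings.catch_warnings():
                # sklearn >= 1.9 deprecation chatter for SVC(probability=True)
                warnings.simplefilter("ignore", FutureWarning)
                clf.fit(X[np.ix_(train, feat)], groups[train])
            Xte = X[np.ix_(test, feat)]
            y_pred = clf.predict(Xte)
            prob = clf.predict_proba(Xte)
            class_order = clf.classes_
            yte = groups[test]
            per_run[n]["accuracy"].append(float(np.mean(y_pred == yte)))
            if binary:
                pos_col = int(np.flatnonzero(class_order == positive)[0])
                per_run[n]["brier"].append(
                    brier_score(yte, prob[:, pos_col], classes=[levels[0], positive])
                )
                cm = confusion_metrics(yte, y_pred, positive)
                for m in ("sensitivity", "specificity", "ppv", "npv"):
                    per_run[n][m].append(cm[m])
            else:
                per_run[n]["brier"].append(brier_score(yte, prob, classes=class_order))

    rows = []
    for n in grid:
        row = {"n_genes": n, "classifier": cfg.classifier}
        for m in metrics:
            vals = np.asarray(per_run[n][m], dtype=float)
            ok = vals[~np.isnan(vals)]
            row[f"{m}_mean"] = float(ok.mean()) if ok.size else np.nan
            row[f"{m}_se"] = (
                float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _rank_for_selection(expr: pd.DataFrame, groups: np.ndarray, levels: np.ndarray):
    """Transcript ranking for selection; binary uses the moderated t, more
    groups use a one-vs-rest best-p combination."""
    if len(levels) == 2:
        return moderated_t_rank(expr, groups)
    pmin = tbest = None
    for g in levels:
        lab = np.where(groups == g, "this", "rest")
        r = moderated_t_rank(expr, lab)
        p = r["p_value"].to_numpy()
        t = np.abs(r["t"].to_numpy())
        if pmin is None:
            pmin, tbest = p.copy(), t.copy()
        else:
            better = p < pmin
            pmin[better] = p[better]
            tbest[better] = t[better]
    out = pd.DataFrame({"t": tbest, "p_value": pmin}, index=expr.index)
    order = np.lexsort((expr.index.astype(str), -tbest, pmin))
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    out["rank"] = ranks
    return out


# --------------------------------------------------------------------- #
# strategies
# --------------------------------------------------------------------- #
def _apply_strategy(ds: ExpressionDataset, spec: StrategySpec) -> ExpressionDataset:
    if spec.strategy == "A":
        return ds
    if spec.strategy == "B":
        if ds.is_true_outlier is None and not spec.true_outlier_ids:
            raise ValueError("strategy B needs known true outliers")
        drop = (
            list(spec.true_outlier_ids)
            if spec.true_outlier_ids
            else ds.sample_ids[ds.is_true_outlier.values].tolist()
        )
        return ds.drop_samples(drop)
    if spec.significant_outlier_ids is None:
        raise ValueError("strategy C needs the significant outliers from the bootstrap")
    return ds.drop_samples(spec.significant_outlier_ids)


def run_strategies(
    ds: ExpressionDataset,
    strategies,
    boot_cfg: BootstrapConfig | None = None,
    eval_cfg: EvalConfig | None = None,
) -> pd.DataFrame:
    """Bootstrap once, then cross-validate every requested strategy.

    ``strategies`` is a list of strategy ids ("A"/"B"/"C") or StrategySpec
    objects.  The outlier table is computed once on the full dataset and
    its significant samples feed strategy C; every strategy's CV uses the
    same evaluation seed, so identical sample subsets give identical rows.
    """
    strategies = [
        s if isinstance(s, StrategySpec) else StrategySpec(strategy=s)
        for s in strategies
    ]
    if not strategies:
        raise ValueError("empty strategy list")
    boot_cfg = boot_cfg or BootstrapConfig()
    eval_cfg = eval_cfg or EvalConfig()

    sig_ids: list | None = None
    if any(s.strategy == "C" and s.significant_outlier_ids is None for s in strategies):
        table = bootstrap_outlier_probabilities(ds, boot_cfg)
        sig_ids = significant_outliers(table, boot_cfg.alpha)

    frames = []
    for spec in strategies:
        if spec.strategy == "C" and spec.significant_outlier_ids is None:
            spec = StrategySpec("C", significant_outlier_ids=sig_ids)
        sub = _apply_strategy(ds, spec)
        if len(set(sub.groups)) < len(set(ds.groups)):
            raise ValueError(
                f"strategy {spec.strategy} removed an entire study group"
            )
        res = cv_evaluate(sub, eval_cfg)
        res.insert(0, "strategy", spec.strategy)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------- #
# DE-overlap report
# --------------------------------------------------------------------- #
def de_overlap_report(
    ds: ExpressionDataset,
    strategy_pair,
    eval_cfg: EvalConfig | None = None,
    boot_cfg: BootstrapConfig | None = None,
    top_n: int = 200,
) -> dict:
    """Stability of the cross-validated top-``top_n`` transcript list.

    For each strategy of the pair, ``n_cv_runs`` random training splits are
    drawn and the per-run top-``top_n`` moderated-t transcripts recorded.
    The report gives, per strategy, the selection frequency of every
    transcript, the two top-``top_n``-by-frequency lists, their
    intersection size and percentage, and the per-transcript frequency
    differences.
    """
    eval_cfg = eval_cfg or EvalConfig()
    specs = [
        s if isinstance(s, StrategySpec) else StrategySpec(strategy=s)
        for s in strategy_pair
    ]
    if len(specs) != 2:
        raise ValueError("strategy_pair must contain exactly two strategies")
    if any(s.strategy == "C" and s.significant_outlier_ids is None for s in specs):
        boot_cfg = boot_cfg or BootstrapConfig()
        table = bootstrap_outlier_probabilities(ds, boot_cfg)
        sig = significant_outliers(table, boot_cfg.alpha)
        specs = [
            StrategySpec("C", significant_outlier_ids=sig)
            if (s.strategy == "C" and s.significant_outlier_ids is None)
            else s
            for s in specs
        ]
    top_n = int(top_n)
    if not 1 <= top_n <= ds.n_transcripts:
        raise ValueError("top_n out of range")

    freqs = []
    for spec in specs:
        sub = _apply_strategy(ds, spec)
        groups = sub.groups.to_numpy()
        levels = np.array(sub.group_levels())
        rng = np.random.default_rng(eval_cfg.seed)
        freq = pd.Series(0, index=ds.transcript_ids, dtype=int)
        for _run in range(eval_cfg.n_cv_runs):
            train, _test = _draw_split(rng, groups, eval_cfg)
            ranking = _rank_for_selection(sub.expression.iloc[:, train], groups[train], levels)
            freq.loc[top_n_transcripts(ranking, top_n)] += 1
        freqs.append(freq)

    def top_by_freq(freq: pd.Series) -> list:
        order = np.lexsort((freq.index.astype(str), -freq.to_numpy()))
        return freq.index[order][:top_n].tolist()

    list_a, list_b = top_by_freq(freqs[0]), top_by_freq(freqs[1])
    inter = sorted(set(list_a) & set(list_b))
    return {
        "strategies": tuple(s.strategy for s in specs),
        "top_n": top_n,
        "frequencies": pd.DataFrame(
            {
                specs[0].strategy: freqs[0],
                specs[1].strategy: freqs[1],
                "difference": freqs[0] - freqs[1],
            }
        ),
        "top_lists": (list_a, list_b),
        "overlap_count": len(inter),
        "overlap_percent": 100.0 * len(inter) / top_n,
    }
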