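"""Count normalization and moderated-t differential-expression ranking.

Raw RNA-Seq counts are brought onto a continuous scale with the log-CPM
transform  log2((count + 0.5) / (library_size + 1) * 1e6)  after dropping
transcripts whose maximum counts-per-million is below 1.

Two-group differential expression uses the empirical-Bayes moderated
t-statistic: per-transcript residual variances s_g^2 (pooled, d residual
degrees of freedom) are modeled as scaled chi-square draws around an
inverse-chi-square prior with scale s0^2 and d0 degrees of freedom.  The
prior parameters are estimated by moment matching on the log residual
variances: with  e_g = log(s_g^2) - digamma(d/2) + log(d/2),

    trigamma(d0/2)   = var(e) - trigamma(d/2)           (solved for d0)
    log(s0^2)        = mean(e) + digamma(d0/2) - log(d0/2),

the posterior variance is the precision-weighted blend

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

and the moderated t  =  (mean2 - mean1) / (s_tilde_g * sqrt(1/n1 + 1/n2))
is referred to a t distribution with d + d0 degrees of freedom.  When the
observed log-variances are *more* concentrated than pure chi-square
sampling noise (non-positive trigamma argument) the prior is taken as
infinitely informative (d0 = inf, full shrinkage to s0^2); when the
moments cannot be estimated at all the statistic degrades to the ordinary
pooled two-sample t (d0 = 0) with a warning.

Transcripts are ranked by ascending p-value (ties: larger |t| first, then
transcript id), and incremental feature selection takes rank prefixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "logcpm_transform",
    "moderated_t_rank",
    "top_n_transcripts",
    "ModeratedTSelector",
]


def logcpm_transform(counts: pd.DataFrame, min_max_cpm: float = 1.0) -> pd.DataFrame:
    """Log2 counts-per-million with pseudo-counts, plus low-expression filter.

    ``counts`` is a transcripts-by-samples frame of non-negative integers.
    Transcripts whose maximum CPM across samples is below ``min_max_cpm``
    are dropped before the transform.
    """
    counts = pd.DataFrame(counts)
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad!r}")
    cpm = vals / lib[None, :] * 1e6
    keep = cpm.max(axis=1) >= min_max_cpm
    vals = vals[keep]
    logcpm = np.log2((vals + 0.5) / (lib[None, :] + 1.0) * 1e6)
    return pd.DataFrame(logcpm, index=counts.index[keep], columns=counts.columns)


# --------------------------------------------------------------------- #
# empirical-Bayes variance moderation
# --------------------------------------------------------------------- #
def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


@dataclass
class _Moderation:
    df_prior: float
    var_prior: float
    var_post: np.ndarray


def _squeeze_variances(s2: np.ndarray, df: float) -> _Moderation:
    """Moment-matching empirical-Bayes shrinkage of residual variances."""
    s2 = np.asarray(s2, dtype=float)
    if df < 1 or not np.all(np.isfinite(np.log(np.maximum(s2, 1e-300)))):
        warnings.warn(
            "cannot estimate the variance prior; using the ordinary t",
            stacklevel=3,
        )
        return _Moderation(0.0, np.nan, s2.copy())
    # work on log variances; guard exact zeros (constant transcripts)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    arg = e_var - float(special.polygamma(1, df / 2.0))
    if arg <= 0:
        df_prior = np.inf
        var_prior = float(np.exp(e_mean))
        var_post = np.full_like(s2, var_prior)
        return _Moderation(df_prior, var_prior, var_post)
    df_prior = 2.0 * _trigamma_inverse(arg)
    var_prior = float(
        np.exp(e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    )
    var_post = (df_prior * var_prior + df * s2) / (df_prior + df)
    return _Moderation(df_prior, var_prior, var_post)


def moderated_t_rank(
    expr: pd.DataFrame, groups, df_prior: float | None = None
) -> pd.DataFrame:
    """Two-group moderated-t ranking of all transcripts.

    ``expr`` is transcripts by samples; ``groups`` must have exactly two
    levels with at least two samples each.  ``df_prior`` overrides the
    estimated prior degrees of freedom (0 gives the ordinary pooled t).

    Returns a frame indexed by transcript id with columns ``t``,
    ``p_value`` and ``rank`` (1 = most significant; ties broken by |t|
    descending, then transcript id).
    """
    expr = pd.DataFrame(expr)
    groups = pd.Series(np.asarray(groups), index=expr.columns)
    levels = sorted(groups.unique().tolist())
    if len(levels) != 2:
        raise ValueError("moderated t requires exactly two groups")
    m1 = groups == levels[0]
    m2 = groups == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    X1 = expr.loc[:, m1.values].to_numpy(dtype=float)
    X2 = expr.loc[:, m2.values].to_numpy(dtype=float)
    mean1, mean2 = X1.mean(axis=1), X2.mean(axis=1)
    df_resid = n1 + n2 - 2
    rss = ((X1 - mean1[:, None]) ** 2).sum(axis=1) + (
        (X2 - mean2[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / df_resid

    if df_prior is None:
        mod = _squeeze_variances(s2, df_resid)
    elif df_prior == 0:
        mod = _Moderation(0.0, np.nan, s2.copy())
    elif np.isinf(df_prior):
        mod = _Moderation(np.inf, float(np.exp(np.mean(np.log(s2)))), None)  # type: ignore
        mod.var_post = np.full_like(s2, mod.var_prior)
    else:
        est = _squeeze_variances(s2, df_resid)
        var_prior = est.var_prior if np.isfinite(est.var_prior) else float(np.median(s2))
        var_post = (df_prior * var_prior + df_resid * s2) / (df_prior + df_resid)
        mod = _Moderation(float(df_prior), var_prior, var_post)

    stderr = np.sqrt(mod.var_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean2 - mean1) / stderr
    df_total = df_resid + mod.df_prior
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isfinite(t), p, 1.0)

    out = pd.DataFrame({"t": t, "p_value": p}, index=expr.index)
    order = np.lexsort(
        (expr.index.astype(str), -np.abs(np.nan_to_num(t)), p)
    )
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    out["rank"] = ranks
    out.attrs["df_prior"] = mod.df_prior
    out.attrs["var_prior"] = mod.var_prior
    out.attrs["df_residual"] = df_resid
    out.attrs["var_post"] = mod.var_post
    out.attrs["s2_residual"] = s2
    return out


def top_n_transcripts(ranking: pd.DataFrame, n: int) -> list:
    """The ``n`` best-ranked transcript ids, in rank order."""
    d = len(ranking)
    if not 1 <= n <= d:
        raise ValueError(f"n={n} out of range 1..{d}")
    return ranking.sort_values("rank").index[:n].tolist()


class ModeratedTSelector(SelectorMixin, BaseEstimator):
    """Feature selector keeping the ``n_features`` most significant columns.

    sklearn orientation: ``X`` is samples by features, ``y`` holds the two
    group labels.  Fitted attributes: ``ranking_`` (frame with t, p-value,
    rank per feature), ``pvalues_``, ``tstats_``.
    """

    def __init__(self, n_features: int = 10):
        self.n_features = n_features

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        expr = pd.DataFrame(X.T)  # transcripts x samples
        self.ranking_ = moderated_t_rank(expr, y)
        self.pvalues_ = self.ranking_["p_value"].to_numpy()
        self.tstats_ = self.ranking_["t"].to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        top = top_n_transcripts(self.ranking_, self.n_features)
        mask[np.asarray(top, dtype=int)] = True
        return mask
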