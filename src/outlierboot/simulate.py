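"""Simulation of expression datasets with planted outlier samples.

Expression values for each transcript are drawn from a normal distribution
around a per-transcript baseline mean.  Two kinds of structure are planted
on top of the baseline:

* **between-group differential expression** — for a chosen subset of
  transcripts the second (and further) groups get their mean multiplied by
  ``2**lambda`` for a nonzero log2 fold change ``lambda``;
* **outlier samples** — a handful of samples per group whose means are
  shifted, in the same multiplicative way, on a second transcript subset
  drawn independently of the differential one.

Planted outliers therefore deviate from their group in directions that are
unrelated to the group contrast, which is what makes them visible as
off-cloud points after dimension reduction while they still carry their
group's signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = ["SimConfig", "shifted_mean", "simulate_dataset", "empirical_group_means"]


@dataclass
class SimConfig:
    """Parameters of the synthetic expression generator.

    Defaults reproduce the two-group design: 1000 transcripts, 50 regular
    samples plus 5 outliers per group (110 samples in total for two groups,
    220 for four), 100 differentially expressed transcripts between groups
    and 50 outlier-shifted transcripts.

    Baseline means are uniform on [4, 12] (a typical log2-expression range),
    nonzero log2 fold changes are uniform on +/-[0.8, 2.0] with random sign,
    and the per-observation noise is Gaussian with a shared standard
    deviation of 1.0.
    """

    n_transcripts: int = 1000
    n_groups: int = 2
    samples_per_group: int = 50
    outliers_per_group: int = 5
    n_de_transcripts: int = 100
    n_outlier_de_transcripts: int = 50
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    lfc_range: tuple[float, float] = (0.8, 2.0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups not in (2, 4):
            raise ValueError("n_groups must be 2 or 4")
        for name in (
            "n_transcripts",
            "samples_per_group",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("outliers_per_group", "n_de_transcripts", "n_outlier_de_transcripts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_de_transcripts > self.n_transcripts:
            raise ValueError("n_de_transcripts cannot exceed n_transcripts")
        if self.n_outlier_de_transcripts > self.n_transcripts:
            raise ValueError("n_outlier_de_transcripts cannot exceed n_transcripts")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.lfc_range
        if lo < 0 or hi < lo:
            raise ValueError("lfc_range must satisfy 0 <= low <= high")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def shifted_mean(mu1: float, lfc: float) -> float:
    """Mean of the contrasted group: ``mu1 * 2**lfc``.

    ``lfc`` is a log2 fold change; ``lfc = 0`` leaves the mean unchanged.
    """
    mu1 = float(mu1)
    if not np.isfinite(mu1) or mu1 <= 0:
        raise ValueError("mu1 must be a positive finite number")
    return mu1 * 2.0 ** float(lfc)


def _draw_lfcs(rng: np.random.Generator, size: int, lfc_range) -> np.ndarray:
    lo, hi = lfc_range
    mag = rng.uniform(lo, hi, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def simulate_dataset(config: SimConfig) -> ExpressionDataset:
    """Generate one synthetic dataset according to ``config``.

    Group means: group 1 keeps the baseline; every further group gets an
    independently drawn set of ``n_de_transcripts`` transcripts with nonzero
    log2 fold change against group 1.  Outlier samples of every group share
    one transcript subset (drawn disjoint from the group-1-vs-2 contrast
    set) on which their group mean is multiplicatively shifted with
    group-specific fold changes.

    The same config (including seed) reproduces the matrix bit for bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    d = cfg.n_transcripts

    baseline = rng.uniform(*cfg.baseline_mean_range, size=d)

    # per-group mean vectors
    group_means = [baseline.copy()]
    de_idx_first = None
    for _g in range(1, cfg.n_groups):
        idx = rng.choice(d, size=cfg.n_de_transcripts, replace=False)
        if de_idx_first is None:
            de_idx_first = idx
        lfc = _draw_lfcs(rng, cfg.n_de_transcripts, cfg.lfc_range)
        mu = baseline.copy()
        mu[idx] = mu[idx] * 2.0 ** lfc
        group_means.append(mu)

    # one outlier transcript subset, disjoint from the group-1-vs-2 contrast
    pool = np.setdiff1d(np.arange(d), de_idx_first if de_idx_first is not None else [])
    if cfg.n_outlier_de_transcripts > pool.size:
        raise ValueError("not enough transcripts outside the DE set for outliers")
    out_idx = rng.choice(pool, size=cfg.n_outlier_de_transcripts, replace=False)

    outlier_means = []
    for g in range(cfg.n_groups):
        lfc = _draw_lfcs(rng, cfg.n_outlier_de_transcripts, cfg.lfc_range)
        mu = group_means[g].copy()
        mu[out_idx] = mu[out_idx] * 2.0 ** lfc
        outlier_means.append(mu)

    cols, labels, flags = [], [], []
    sample_names = []
    for g in range(cfg.n_groups):
        gname = f"group{g + 1}"
        n_reg, n_out = cfg.samples_per_group, cfg.outliers_per_group
        mu_reg = group_means[g][:, None]
        reg = mu_reg + rng.normal(0.0, cfg.noise_sd, size=(d, n_reg))
        cols.append(reg)
        labels += [gname] * n_reg
        flags += [False] * n_reg
        sample_names += [f"{gname}_s{i + 1:03d}" for i in range(n_reg)]
        if n_out:
            mu_out = outlier_means[g][:, None]
            out = mu_out + rng.normal(0.0, cfg.noise_sd, size=(d, n_out))
            cols.append(out)
            labels += [gname] * n_out
            flags += [True] * n_out
            sample_names += [f"{gname}_o{i + 1:03d}" for i in range(n_out)]

    matrix = np.concatenate(cols, axis=1)
    transcript_ids = [f"t{i + 1:05d}" for i in range(d)]
    expr = pd.DataFrame(matrix, index=transcript_ids, columns=sample_names)
    return ExpressionDataset(
        expression=expr,
        groups=pd.Series(labels, index=sample_names),
        is_true_outlier=pd.Series(flags, index=sample_names),
    )


def empirical_group_means(ds: ExpressionDataset, group) -> pd.Series:
    """Per-transcript mean over the non-outlier samples of one group."""
    mask = ds.groups == group
    if not mask.any():
        raise KeyError(f"unknown group label: {group!r}")
    if ds.is_true_outlier is not None:
        mask &= ~ds.is_true_outlier
    if not mask.any():
        raise ValueError(f"group {group!r} has no regular samples")
    return ds.expression.loc[:, mask.values].mean(axis=1)
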