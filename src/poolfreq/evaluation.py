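"""Accuracy machinery: MAE, cross-validation, replicate concordance.

Two cross-validation schemes probe the calibration curve.  The SNP k-fold
scheme refits on 800 of the 1000 calibration SNPs and predicts the
controlled pools of the held-out 200, measuring sensitivity to the SNP
sample.  The sample-removal scheme removes k of the 18 controlled-pool
samples, refits on the remainder, and predicts the removed pools,
measuring sensitivity to the covered frequency range (error grows as the
remaining pools span less of it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .calibration import CalibrationData, fit_logistic, predict_frequency
from .io import FrequencyMatrix

__all__ = [
    "MAEReport",
    "mean_absolute_error",
    "snp_kfold_cv",
    "sample_removal_cv",
    "replicate_concordance",
]

DEFAULT_BINS = tuple(np.linspace(0.0, 1.0, 22))  # 21 equal bins over [0, 1]


@dataclass(frozen=True)
class MAEReport:
    """Mean absolute error between predicted and expected frequencies.

    ``sd`` is the dispersion companion of ``mae`` (across cells for a plain
    comparison, across repeats for a cross-validation scheme); ``breakdown``
    maps expected-frequency bins to their bin-wise MAE.
    """

    mae: float
    sd: float
    n_cells: int
    breakdown: dict[tuple[float, float], float]


def _as_frame(m) -> pd.DataFrame:
    return m.values if isinstance(m, FrequencyMatrix) else pd.DataFrame(m)


def _binned_mae(err: np.ndarray, expected: np.ndarray,
                bins: Sequence[float]) -> dict[tuple[float, float], float]:
    edges = np.asarray(bins, dtype=float)
    out: dict[tuple[float, float], float] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        sel = (expected >= lo) & ((expected <= hi) if last else (expected < hi))
        out[(float(lo), float(hi))] = float(err[sel].mean()) if sel.any() else math.nan
    return out


def mean_absolute_error(predicted, expected,
                        bins: Sequence[float] = DEFAULT_BINS) -> MAEReport:
    """MAE over all cells present in both matrices (pairwise-complete),
    with a breakdown by expected-frequency bin."""
    pred = _as_frame(predicted)
    exp = _as_frame(expected)
    snps = pred.index.intersection(exp.index)
    cols = pred.columns.intersection(exp.columns)
    p = pred.loc[snps, cols].to_numpy(dtype=float).ravel()
    e = exp.loc[snps, cols].to_numpy(dtype=float).ravel()
    ok = ~(np.isnan(p) | np.isnan(e))
    if not ok.any():
        raise ValueError("no overlapping non-missing cells")
    err = np.abs(p[ok] - e[ok])
    sd = float(err.std(ddof=1)) if err.size > 1 else 0.0
    return MAEReport(float(err.mean()), sd, int(err.size),
                     _binned_mae(err, e[ok], bins))


def snp_kfold_cv(calibration_data: CalibrationData, train_n: int = 800,
                 test_n: int = 200, repeats: int = 5,
                 seed: int | None = None) -> list[MAEReport]:
    """Repeated SNP-holdout validation of the common calibration curve.

    Per repeat: fit on a random ``train_n``-SNP subset (all calibration
    samples), predict the controlled pools of the remaining ``test_n``
    SNPs, and report the MAE against their expected frequencies.
    """
    snps = list(calibration_data.fir.index)
    if train_n + test_n > len(snps):
        raise ValueError("train_n + test_n exceeds the calibration SNP count")
    rng = np.random.default_rng(seed)
    reports: list[MAEReport] = []
    pool_cols = calibration_data.pool_samples or list(calibration_data.fir.columns)
    for _ in range(repeats):
        perm = rng.permutation(len(snps))
        train = [snps[i] for i in perm[:train_n]]
        test = [snps[i] for i in perm[train_n:train_n + test_n]]
        x_tr, y_tr = calibration_data.pairs(train)
        fit = fit_logistic(x_tr, y_tr)
        x_te, y_te = calibration_data.pairs(test, pool_cols)
        err = np.abs(predict_frequency(x_te, fit) - y_te)
        reports.append(MAEReport(float(err.mean()),
                                 float(err.std(ddof=1)) if err.size > 1 else 0.0,
                                 int(err.size), _binned_mae(err, y_te, DEFAULT_BINS)))
    return reports


def sample_removal_cv(calibration_data: CalibrationData, k_removed: int,
                      repeats: int = 1000, seed: int | None = None
                      ) -> MAEReport:
    """Remove ``k_removed`` controlled-pool samples at random, refit, and
    predict the removed pools; mean and sd of the per-repeat MAE.
    """
    pools = list(calibration_data.pool_samples)
    if not pools:
        raise ValueError("calibration data declares no pool samples")
    if not 1 <= k_removed < len(pools):
        raise ValueError(f"k_removed must be in [1, {len(pools) - 1}]")
    rng = np.random.default_rng(seed)
    keep_always = calibration_data.parent_samples
    maes = np.empty(repeats)
    n_cells = 0
    all_err: list[np.ndarray] = []
    all_exp: list[np.ndarray] = []
    for r in range(repeats):
        removed_idx = rng.choice(len(pools), size=k_removed, replace=False)
        removed = [pools[i] for i in removed_idx]
        kept = [p for p in pools if p not in set(removed)] + keep_always
        x_tr, y_tr = calibration_data.pairs(None, kept)
        fit = fit_logistic(x_tr, y_tr)
        x_te, y_te = calibration_data.pairs(None, removed)
        err = np.abs(predict_frequency(x_te, fit) - y_te)
        maes[r] = err.mean()
        n_cells += err.size
        all_err.append(err)
        all_exp.append(y_te)
    err_cat = np.concatenate(all_err)
    exp_cat = np.concatenate(all_exp)
    sd = float(maes.std(ddof=1)) if repeats > 1 else 0.0
    return MAEReport(float(maes.mean()), sd, int(n_cells),
                     _binned_mae(err_cat, exp_cat, DEFAULT_BINS))


def replicate_concordance(f1: Sequence[float], f2: Sequence[float],
                          n_individuals: int = 15,
                          conf: float = 0.95) -> float:
    """Fraction of SNPs whose two biological-replicate frequencies agree
    within the sampling-only limit.

    Each replicate draws 2*n_individuals gametes, so under pure sampling
    the difference d = f1 - f2 at pooled estimate m = (f1 + f2)/2 is
    approximately Normal(0, 2*m*(1-m)/(2n)).  A pair is concordant when
    |d| is inside the two-sided ``conf`` limit of that distribution.
    """
    a = np.asarray(f1, dtype=float)
    b = np.asarray(f2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no paired non-missing frequencies")
    m = (a + b) / 2.0
    z = _norm.ppf(1.0 - (1.0 - conf) / 2.0)
    half_width = z * np.sqrt(2.0 * m * (1.0 - m) / (2.0 * n_individuals))
    inside = np.abs(a - b) <= half_width + 1e-12
    return float(inside.mean())
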