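"""Step 2 calibration: controlled pools and the common logistic curve.

Controlled pools mix leaf material of three fully homozygous parental
lines (L1, L2, L3) in known mass proportions, so the expected allele-B
frequency of a pool at a SNP is the proportion-weighted sum of the
parents' allele-B dosages (0 or 1).  Nine standard proportion triples,
applied to two independent parental trios ("series"), span expected
frequencies from 1% to 99%.

Depending on the three parental genotypes a SNP falls in one of four
polymorphic configuration classes, each covering a frequency range across
the nine pools:

    R1: (B,A,A)            ->  1-33%
    R2: (A,A,B)/(A,B,A)    -> 33-50%
    R3: (B,A,B)/(B,B,A)    -> 51-67%
    R4: (A,B,B)            -> 67-99%

The calibration sample takes 250 SNPs per class (1000 total) so that
every part of the frequency range is represented, and a single logistic
curve

    logit(f_B) = alpha + beta * FIR

is fitted to all (FIR, expected frequency) pairs at once by iteratively
reweighted least squares with fractional (quasi-binomial) responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, xlogy

__all__ = [
    "MONO_A",
    "MONO_B",
    "CONFIG_CLASSES",
    "PoolDesign",
    "CalibrationFit",
    "CalibrationData",
    "STANDARD_PROPORTIONS",
    "standard_pool_designs",
    "expected_pool_frequency",
    "expected_pool_percent",
    "classify_configuration",
    "select_calibration_snps",
    "fit_logistic",
    "predict_frequency",
]

MONO_A = "MONO_A"
MONO_B = "MONO_B"
CONFIG_CLASSES = ("R1", "R2", "R3", "R4")

# Leaf-mass proportion triples (L1, L2, L3) of the nine standard pools;
# L2 and L3 vary together while L1 varies inversely.
STANDARD_PROPORTIONS: tuple[tuple[float, float, float], ...] = (
    (0.01, 0.495, 0.495),
    (0.02, 0.49, 0.49),
    (0.03, 0.485, 0.485),
    (0.05, 0.475, 0.475),
    (0.07, 0.465, 0.465),
    (0.10, 0.45, 0.45),
    (0.15, 0.425, 0.425),
    (0.20, 0.40, 0.40),
    (1 / 3, 1 / 3, 1 / 3),
)

_CONFIG_BY_DOSAGE: dict[tuple[int, int, int], str] = {
    (0, 0, 0): MONO_A,
    (1, 0, 0): "R1",
    (0, 0, 1): "R2",
    (0, 1, 0): "R2",
    (1, 0, 1): "R3",
    (1, 1, 0): "R3",
    (0, 1, 1): "R4",
    (1, 1, 1): MONO_B,
}


@dataclass(frozen=True)
class PoolDesign:
    """One controlled pool: mass proportions of the three parents."""

    pool_id: str
    proportions: tuple[float, float, float]
    series_id: str

    def __post_init__(self) -> None:
        if len(self.proportions) != 3:
            raise ValueError("a pool mixes exactly three parental lines")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("pool proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("pool proportions must be non-negative")


def standard_pool_designs(series_id: str) -> list[PoolDesign]:
    """The nine standard proportion triples for one parental trio."""
    return [
        PoolDesign(f"#{i + 1}", props, series_id)
        for i, props in enumerate(STANDARD_PROPORTIONS)
    ]


def expected_pool_frequency(parent_genotypes: Sequence[int],
                            proportions: Sequence[float]) -> float:
    """Proportion-weighted allele-B frequency of a controlled pool.

    ``parent_genotypes`` are allele-B dosages in {0, 1} (heterozygous
    parents must be filtered out upstream).
    """
    if len(parent_genotypes) != 3 or len(proportions) != 3:
        raise ValueError("expected three parents")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    for d in parent_genotypes:
        if d not in (0, 1):
            raise ValueError(f"parental dosage must be 0 or 1, got {d!r}")
    return float(sum(p * d for p, d in zip(proportions, parent_genotypes)))


def expected_pool_percent(parent_genotypes: Sequence[int],
                          proportions: Sequence[float]) -> int:
    """Expected pool frequency as a whole percent, rounded half away from
    zero (0.575 -> 58%).

    The value is snapped to 9 decimals first so that binary representation
    error (0.15 + 0.425 = 0.5749999...) cannot flip the rounding.
    """
    f = expected_pool_frequency(parent_genotypes, proportions)
    return int(math.floor(round(f * 100.0, 9) + 0.5))


def classify_configuration(parent_genotypes: Sequence[int]) -> str:
    """Map a parental dosage triple to its configuration class."""
    key = tuple(int(d) for d in parent_genotypes)
    if any(d not in (0, 1) for d in key) or len(key) != 3:
        raise ValueError(f"invalid parental dosages {parent_genotypes!r}")
    return _CONFIG_BY_DOSAGE[key]


# R1/R4 first: SNPs reaching the extreme frequency ranges are preferred,
# maximising the frequency span of the calibration sample.
_CLASS_PRIORITY = ("R1", "R4", "R2", "R3")


def select_calibration_snps(
    configs_by_snp: Mapping[str, Sequence[str]],
    n_per_class: int = 250,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Draw the calibration sample: ``n_per_class`` SNPs per configuration
    class R1-R4, each SNP assigned to exactly one class.

    ``configs_by_snp`` maps a SNP id to its configuration class in each
    series.  A SNP showing different classes across series is assigned by
    the priority order R1, R4, R2, R3 (extreme ranges first); monomorphic
    configurations never qualify.  Sampling is uniform without replacement
    and reproducible for a given seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    by_class: dict[str, list[str]] = {c: [] for c in CONFIG_CLASSES}
    for snp in sorted(configs_by_snp):
        configs = set(configs_by_snp[snp])
        for cls in _CLASS_PRIORITY:
            if cls in configs:
                by_class[cls].append(snp)
                break
    selected: list[str] = []
    for cls in CONFIG_CLASSES:
        pool = by_class[cls]
        if len(pool) < n_per_class:
            raise ValueError(
                f"class {cls}: only {len(pool)} eligible SNPs, "
                f"need {n_per_class}")
        idx = rng.choice(len(pool), size=n_per_class, replace=False)
        selected.extend(pool[i] for i in sorted(idx))
    return selected


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted intercept/slope of the common logit-link calibration curve."""

    alpha: float
    beta: float
    n_obs: int
    deviance: float
    converged: bool
    n_iter: int = 0


@dataclass
class CalibrationData:
    """The calibration design: FIR and expected frequency per SNP x sample.

    ``pool_samples`` lists the controlled-pool columns (the units removed in
    sample-removal cross-validation); remaining columns are parental lines.
    """

    fir: pd.DataFrame
    expected: pd.DataFrame
    pool_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.fir.index.equals(self.expected.index)
                and self.fir.columns.equals(self.expected.columns)):
            raise ValueError("FIR and expected matrices must be aligned")
        unknown = set(self.pool_samples) - set(map(str, self.fir.columns))
        if unknown:
            raise ValueError(f"unknown pool samples {sorted(unknown)}")

    @property
    def parent_samples(self) -> list[str]:
        pools = set(self.pool_samples)
        return [c for c in self.fir.columns if c not in pools]

    def pairs(self, snp_ids: Iterable[str] | None = None,
              sample_ids: Iterable[str] | None = None,
              polymorphic_only: bool = False
              ) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to paired (FIR, expected-frequency) vectors, dropping
        cells missing on either side.

        ``polymorphic_only`` restricts to cells with expected frequency
        strictly inside (0, 1) — cells where the logistic response is not
        saturated.
        """
        fir = self.fir if snp_ids is None else self.fir.loc[list(snp_ids)]
        exp = self.expected if snp_ids is None else self.expected.loc[list(snp_ids)]
        if sample_ids is not None:
            fir = fir[list(sample_ids)]
            exp = exp[list(sample_ids)]
        x = fir.to_numpy(dtype=float).ravel()
        y = exp.to_numpy(dtype=float).ravel()
        ok = ~(np.isnan(x) | np.isnan(y))
        if polymorphic_only:
            ok &= (y > 0.0) & (y < 1.0)
        return x[ok], y[ok]


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # fractional responses: 0*log(0) terms vanish
    return float(2.0 * np.sum(
        xlogy(y, y) - xlogy(y, mu) + xlogy(1 - y, 1 - y) - xlogy(1 - y, 1 - mu)
    ))


def fit_logistic(fir_obs: Sequence[float], expected_freq: Sequence[float],
                 tol: float = 1e-10, max_iter: int = 50) -> CalibrationFit:
    """Fit logit(f) = alpha + beta*FIR by IRLS with fractional responses.

    Minimises the binomial deviance with unit observation weights
    (quasi-binomial likelihood: responses may be any value in [0, 1]).
    Convergence: relative deviance change below ``tol`` (or deviance
    numerically zero) within ``max_iter`` iterations; otherwise the fit is
    returned with ``converged=False``.
    """
    x = np.asarray(fir_obs, dtype=float)
    y = np.asarray(expected_freq, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fir_obs and expected_freq must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed in the fit")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("expected frequencies must lie in [0, 1]")
    if np.unique(y).size < 2:
        raise ValueError("expected frequencies are all identical: "
                         "no slope is identifiable")

    X = np.column_stack([np.ones_like(x), x])
    mu = np.clip(y, 0.005, 0.995)
    eta = logit(mu)
    dev = _binomial_deviance(y, mu)
    coef = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ coef
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        new_dev = _binomial_deviance(y, mu)
        if not np.isfinite(new_dev):
            break
        if abs(dev - new_dev) <= tol * (abs(new_dev) + 0.1) or new_dev < 1e-14:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    alpha, beta = (float(coef[0]), float(coef[1]))
    if not (math.isfinite(alpha) and math.isfinite(beta)):
        converged = False
    return CalibrationFit(alpha, beta, int(x.size), float(dev), converged, it)


def predict_frequency(fir_obs, fit: CalibrationFit):
    """Invert the calibration curve: f = expit(alpha + beta*FIR).

    Returns values strictly inside (0, 1); accepts scalars or arrays.
    """
    if not fit.converged:
        raise ValueError("calibration fit did not converge")
    eta = fit.alpha + fit.beta * np.asarray(fir_obs, dtype=float)
    p = expit(eta)
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, np.nextafter(1.0, 0.0))
    if np.ndim(fir_obs) == 0:
        return float(p)
    return p
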