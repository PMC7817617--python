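"""Exact binomial (Clopper-Pearson) bounds for individual-sampling error.

A bulk of n diploid individuals carries 2n sampled gametes, so even a
perfect frequency measurement is only a binomial estimate of the
population frequency.  The 95% bounds below quantify that sampling error:
with x = round(freq * n_gametes) observed B alleles out of
n_gametes = 2 * individuals * replicates,

    lower = BetaInv((1-conf)/2;   x,   n-x+1)   (0 when x = 0)
    upper = BetaInv(1-(1-conf)/2; x+1, n-x)     (1 when x = n)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import beta as _beta

__all__ = [
    "ConfidenceBounds",
    "sampling_confidence_interval",
    "sampling_table",
    "DEFAULT_TABLE_FREQS",
]

DEFAULT_TABLE_FREQS = (0.0, 0.03, 0.1, 0.2, 0.3, 0.4, 0.5,
                       0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class ConfidenceBounds:
    true_freq: float
    n_individuals: int
    n_replicates: int
    lower: float
    upper: float
    x: int
    n: int


def _round_half_away(v: float) -> int:
    return int(v + 0.5) if v >= 0 else -int(-v + 0.5)


def sampling_confidence_interval(freq: float, n_individuals: int,
                                 n_replicates: int = 1,
                                 conf: float = 0.95) -> ConfidenceBounds:
    """Exact Clopper-Pearson bounds for the population allele frequency.

    ``n_replicates`` biological replicates of ``n_individuals`` pool their
    gametes, so the binomial size is 2 * individuals * replicates.  The
    observed count is the nearest integer to ``freq * n`` (half away from
    zero).
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must lie in [0, 1]")
    if n_individuals < 1 or n_replicates < 1:
        raise ValueError("individuals and replicates must be >= 1")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    n = 2 * n_individuals * n_replicates
    x = _round_half_away(freq * n)
    a = 1.0 - conf
    lower = 0.0 if x == 0 else float(_beta.ppf(a / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(_beta.ppf(1 - a / 2, x + 1, n - x))
    return ConfidenceBounds(freq, n_individuals, n_replicates, lower, upper,
                            x, n)


def sampling_table(freqs: Sequence[float] = DEFAULT_TABLE_FREQS,
                   n_individuals_list: Sequence[int] = (15, 100),
                   n_replicates_list: Sequence[int] = (1, 2),
                   conf: float = 0.95) -> pd.DataFrame:
    """Bounds for the Cartesian grid of frequencies x individuals x
    replicates, one row per combination."""
    rows = []
    for f in freqs:
        for ni in n_individuals_list:
            for nr in n_replicates_list:
                b = sampling_confidence_interval(f, ni, nr, conf)
                rows.append((f, ni, nr, b.lower, b.upper))
    return pd.DataFrame(rows, columns=[
        "freq", "n_individuals", "n_replicates", "lower", "upper"])
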