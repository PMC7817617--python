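"""Modified Roger's Distance (MRD) between populations.

For m loci with allele-frequency vectors p and q,

    MRD(p, q) = sqrt( (1/2m) * sum_loci sum_alleles (p_a - q_a)^2 )

which for biallelic loci collapses to sqrt((1/m) * sum (pB - qB)^2).
MRD is Euclidean up to the 1/sqrt(2m) scaling, hence a metric, and lies
in [0, 1] with 1 reached when every locus is differentially fixed.

The pre-processing mirrors the intended workflow: replicate bulks of the
same population are averaged (pairwise-complete), then missing cells are
imputed with the across-population mean frequency of the SNP, and only
then are (optionally random) SNP subsets taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FrequencyMatrix

__all__ = [
    "DistanceMatrix",
    "impute_missing_frequencies",
    "merge_replicates",
    "mrd",
    "mrd_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    population_ids: list[str]
    d: np.ndarray
    m_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.population_ids,
                            columns=self.population_ids)


def _as_frame(fm) -> pd.DataFrame:
    return fm.values if isinstance(fm, FrequencyMatrix) else pd.DataFrame(fm)


def impute_missing_frequencies(fm) -> pd.DataFrame:
    """Replace each missing cell by its SNP's mean frequency across
    populations; SNPs missing everywhere are dropped (logged)."""
    df = _as_frame(fm).astype(float)
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d SNPs with no observed frequency",
                       int(all_missing.sum()))
        df = df.loc[~all_missing]
    row_means = df.mean(axis=1, skipna=True)
    return df.apply(lambda col: col.fillna(row_means))


def merge_replicates(fm, replicate_map: Mapping[str, Sequence[str]],
                     excluded_samples: Iterable[str] = ()) -> pd.DataFrame:
    """Average replicate sample columns into one column per population.

    Averaging is pairwise-complete per SNP: when one replicate is missing
    the other's value passes through.  ``excluded_samples`` are dropped
    before averaging; samples not covered by the map pass through under
    their own id.
    """
    df = _as_frame(fm).astype(float)
    excluded = set(excluded_samples)
    df = df.drop(columns=[c for c in df.columns if c in excluded])
    mapped: set[str] = set()
    out: dict[str, pd.Series] = {}
    for pop, samples in replicate_map.items():
        present = [s for s in samples if s not in excluded]
        unknown = set(present) - set(df.columns)
        if unknown:
            raise ValueError(f"replicate map for {pop!r} references unknown "
                             f"samples {sorted(unknown)}")
        mapped.update(present)
        out[pop] = df[present].mean(axis=1, skipna=True)
    for col in df.columns:
        if col not in mapped:
            out[str(col)] = df[col]
    return pd.DataFrame(out)


def mrd(p: Sequence[float], q: Sequence[float]) -> float:
    """Modified Roger's Distance between two allele-B frequency vectors."""
    a = np.asarray(p, dtype=float)
    b = np.asarray(q, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("frequency vectors must be equal-length 1-D")
    if a.size == 0:
        raise ValueError("need at least one locus")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing frequencies: impute before computing MRD")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mrd_matrix(fm, snp_subset: Iterable[str] | None = None,
               subset_n: int | None = None,
               seed: int | None = None) -> DistanceMatrix:
    """Pairwise MRD over all populations, optionally on a SNP subset.

    ``snp_subset`` selects named SNPs; ``subset_n`` instead draws that many
    SNPs uniformly without replacement (seeded).  Frequencies must be
    complete (run :func:`impute_missing_frequencies` first).
    """
    df = _as_frame(fm).astype(float)
    if snp_subset is not None:
        subset = [s for s in df.index if s in set(snp_subset)]
        if not subset:
            raise ValueError("SNP subset is empty")
        df = df.loc[subset]
    if subset_n is not None:
        if not 1 <= subset_n <= len(df):
            raise ValueError("subset_n out of range")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(df), size=subset_n, replace=False))
        df = df.iloc[idx]
    if df.isna().any().any():
        raise ValueError("missing frequencies: impute before computing MRD")
    pops = [str(c) for c in df.columns]
    x = df.to_numpy(dtype=float).T  # populations x loci
    n, m = x.shape
    d = np.zeros((n, n))
    for i in range(n):
        diff = x[i + 1:] - x[i]
        d[i, i + 1:] = np.sqrt(np.mean(diff ** 2, axis=1))
    d = d + d.T
    m_used = np.full((n, n), m, dtype=int)
    np.fill_diagonal(m_used, m)
    return DistanceMatrix(pops, d, m_used)
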