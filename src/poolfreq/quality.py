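"""SNP quality scoring by cluster separation (weighted deviation, wd).

For each SNP, the FIR values of reference inbred lines called AA and BB
form two clusters.  The wd score measures how separable they are:

    wd = |mu_AA - mu_BB| / sqrt((N_AA*sd_AA^2 + N_BB*sd_BB^2) / (N_AA + N_BB))

SNPs whose clusters overlap or are noisy (low wd) give unreliable frequency
estimates from FIR and are removed.  SNPs monomorphic in the reference panel
are still scorable by substituting the theoretical FIR of the absent
homozygote class: mu_AA = 0 (sd 0) when no AA lines exist, mu_BB = 1 (sd 0)
when no BB lines exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import FIRMatrix, GenotypeCallMatrix

__all__ = [
    "ClusterStats",
    "WdRecord",
    "compute_cluster_stats",
    "weighted_deviation",
    "filter_snps",
]


@dataclass(frozen=True)
class ClusterStats:
    """Per-SNP FIR summary of the AA and BB homozygote reference clusters.

    Standard deviations use the n-1 (sample) convention and are NaN when a
    cluster has fewer than two members.
    """

    snp_id: str
    mu_aa: float
    sd_aa: float
    n_aa: int
    mu_bb: float
    sd_bb: float
    n_bb: int


@dataclass(frozen=True)
class WdRecord:
    snp_id: str
    wd: float  # may be +inf (zero pooled variance) or NaN (undefined)
    monomorphic_side: str  # one of "none", "AA_only", "BB_only"


def compute_cluster_stats(fir: FIRMatrix, calls: GenotypeCallMatrix
                          ) -> list[ClusterStats]:
    """Summarise homozygote-cluster FIR per SNP from reference-panel calls.

    Only samples called AA or BB with a non-missing FIR contribute; AB and
    missing calls are excluded.  SNP and sample universes are intersected.
    """
    snps = [s for s in fir.snp_ids if s in set(calls.snp_ids)]
    samples = [s for s in fir.sample_ids if s in set(calls.sample_ids)]
    if not snps or not samples:
        raise ValueError("FIR matrix and call matrix share no SNPs/samples")
    f = fir.values.loc[snps, samples].to_numpy(dtype=float)
    c = calls.calls.loc[snps, samples].to_numpy(dtype=object)

    out: list[ClusterStats] = []
    for i, snp in enumerate(snps):
        row = f[i]
        stats = {}
        for geno in ("AA", "BB"):
            sel = (c[i] == geno) & ~np.isnan(row)
            vals = row[sel]
            n = int(vals.size)
            mu = float(vals.mean()) if n else math.nan
            sd = float(vals.std(ddof=1)) if n > 1 else math.nan
            stats[geno] = (mu, sd, n)
        out.append(ClusterStats(snp, *stats["AA"], *stats["BB"]))
    return out


def _var_term(sd: float, n: int) -> float:
    # n <= 1 clusters carry no usable spread estimate: contribute N*sd^2 = 0
    if n <= 1 or math.isnan(sd):
        return 0.0
    return n * sd * sd


def weighted_deviation(cs: ClusterStats) -> WdRecord:
    """Score cluster separation for one SNP.

    Monomorphic SNPs use the theoretical-homozygote substitution for the
    absent cluster.  A zero pooled variance with distinct means yields +inf
    (perfect separation); when neither cluster has two members the score is
    undefined (NaN).
    """
    mu_aa, sd_aa, n_aa = cs.mu_aa, cs.sd_aa, cs.n_aa
    mu_bb, sd_bb, n_bb = cs.mu_bb, cs.sd_bb, cs.n_bb
    side = "none"
    if n_aa == 0 and n_bb == 0:
        return WdRecord(cs.snp_id, math.nan, "none")
    if n_aa == 0:
        mu_aa, sd_aa = 0.0, 0.0
        side = "BB_only"
    elif n_bb == 0:
        mu_bb, sd_bb = 1.0, 0.0
        side = "AA_only"
    if max(n_aa, n_bb) < 2:
        return WdRecord(cs.snp_id, math.nan, side)
    pooled = (_var_term(sd_aa, n_aa) + _var_term(sd_bb, n_bb)) / (n_aa + n_bb)
    num = abs(mu_aa - mu_bb)
    if pooled == 0.0:
        wd = math.inf if num > 0 else math.nan
    else:
        wd = num / math.sqrt(pooled)
    return WdRecord(cs.snp_id, wd, side)


def filter_snps(wds: Iterable[WdRecord], threshold: float = 50.0,
                het_in_calibration_parents: Iterable[str] = (),
                ) -> set[str]:
    """Keep SNPs with wd strictly above ``threshold``.

    SNPs heterozygous in any calibration-pool parental line are removed
    regardless of wd, since their expected pool frequencies are undefined.
    +inf wd passes; undefined (NaN) wd fails.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    het = set(het_in_calibration_parents)
    kept: set[str] = set()
    for rec in wds:
        if rec.snp_id in het:
            continue
        if not math.isnan(rec.wd) and rec.wd > threshold:
            kept.add(rec.snp_id)
    return kept


def wd_table(wds: Sequence[WdRecord]) -> pd.DataFrame:
    """Tabulate wd records (snp_id index; wd, monomorphic_side columns)."""
    return pd.DataFrame(
        {"wd": [w.wd for w in wds],
         "monomorphic_side": [w.monomorphic_side for w in wds]},
        index=pd.Index([w.snp_id for w in wds], name="snp_id"),
    )


def cluster_stats_table(stats: Sequence[ClusterStats]) -> pd.DataFrame:
    """Tabulate cluster statistics for TSV export."""
    return pd.DataFrame(
        {k: [getattr(s, k) for s in stats]
         for k in ("mu_aa", "sd_aa", "n_aa", "mu_bb", "sd_bb", "n_bb")},
        index=pd.Index([s.snp_id for s in stats], name="snp_id"),
    )


def cluster_stats_from_table(df: pd.DataFrame) -> list[ClusterStats]:
    """Inverse of :func:`cluster_stats_table`."""
    return [
        ClusterStats(str(idx), float(r.mu_aa), float(r.sd_aa), int(r.n_aa),
                     float(r.mu_bb), float(r.sd_bb), int(r.n_bb))
        for idx, r in df.iterrows()
    ]
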