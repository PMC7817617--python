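"""The end-to-end two-step frequency estimator.

Per kept SNP and per bulk: first test allele fixation against the
reference homozygote clusters; only bulks declared polymorphic get a
frequency from the logistic calibration curve.  Fixed bulks receive an
exact 0 or 1, which is what protects diversity analyses from spurious
allele detection — the calibration curve alone can never output 0 or 1.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from . import fixation as fx
from .calibration import CalibrationFit, predict_frequency
from .io import (FIRMatrix, FrequencyMatrix, SOURCE_AMBIGUOUS, SOURCE_FIXED,
                 SOURCE_LOGISTIC, SOURCE_MISSING)
from .quality import ClusterStats

__all__ = ["estimate_frequencies", "fixation_calls_table"]

logger = logging.getLogger(__name__)


def _stats_by_snp(cluster_stats: Iterable[ClusterStats]
                  ) -> dict[str, ClusterStats]:
    return {cs.snp_id: cs for cs in cluster_stats}


def _row_membership(obs: np.ndarray, mu: float, sd: float, n: int,
                    alpha: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised single-observation membership test over one SNP row."""
    t = np.full(obs.shape, np.nan)
    p = np.full(obs.shape, np.nan)
    ok = ~np.isnan(obs)
    if sd == 0.0 or math.isnan(sd) or n < 2:
        eq = ok & (obs == mu)
        t[ok] = np.where(eq[ok], 0.0, np.inf)
        p[ok] = np.where(eq[ok], 1.0, 0.0)
    else:
        t[ok] = (obs[ok] - mu) / (sd * math.sqrt(1.0 + 1.0 / n))
        p[ok] = 2.0 * _st.t.sf(np.abs(t[ok]), n - 1)
    member = np.zeros(obs.shape, dtype=bool)
    member[ok] = p[ok] >= alpha
    return t, p, member


def estimate_frequencies(fir_bulks: FIRMatrix,
                         cluster_stats: Iterable[ClusterStats] | Mapping[str, ClusterStats],
                         fit: CalibrationFit,
                         kept_snps: Iterable[str],
                         alpha: float = 0.05,
                         emit_calls: bool = False):
    """Run the two-step estimator over all kept SNPs and all bulks.

    Returns a :class:`FrequencyMatrix` (and, when ``emit_calls`` is true,
    a second DataFrame with per-cell fixation calls and test statistics).
    Kept SNPs without cluster statistics are skipped with a logged count.
    """
    if not fit.converged:
        raise ValueError("calibration fit did not converge")
    stats = (dict(cluster_stats) if isinstance(cluster_stats, Mapping)
             else _stats_by_snp(cluster_stats))
    kept = set(kept_snps)
    unknown = kept - set(fir_bulks.snp_ids)
    if unknown:
        raise ValueError(f"kept SNPs absent from bulk FIR matrix: "
                         f"{sorted(unknown)[:5]} ...")
    snps = [s for s in fir_bulks.snp_ids if s in kept]
    n_skipped = 0
    rows_f, rows_s, used_snps = [], [], []
    call_rows = [] if emit_calls else None
    samples = fir_bulks.sample_ids

    for snp in snps:
        cs = stats.get(snp)
        if cs is None:
            n_skipped += 1
            continue
        obs = fir_bulks.values.loc[snp].to_numpy(dtype=float)

        mu_a, sd_a, n_a = cs.mu_aa, cs.sd_aa, cs.n_aa
        mu_b, sd_b, n_b = cs.mu_bb, cs.sd_bb, cs.n_bb
        if n_a == 0:
            mu_a, sd_a, n_a = 0.0, cs.sd_bb, cs.n_bb
        if n_b == 0:
            mu_b, sd_b, n_b = 1.0, cs.sd_aa, cs.n_aa
        if n_a == 0 and n_b == 0:
            n_skipped += 1
            continue

        t_a, p_a, mem_a = _row_membership(obs, mu_a, sd_a, n_a, alpha)
        t_b, p_b, mem_b = _row_membership(obs, mu_b, sd_b, n_b, alpha)
        missing = np.isnan(obs)
        ambiguous = mem_a & mem_b & ~missing
        fixed_a = mem_a & ~mem_b & ~missing
        fixed_b = mem_b & ~mem_a & ~missing
        poly = ~mem_a & ~mem_b & ~missing

        freq = np.full(obs.shape, np.nan)
        freq[fixed_a] = 0.0
        freq[fixed_b] = 1.0
        if np.any(poly):
            freq[poly] = predict_frequency(obs[poly], fit)
        source = np.full(obs.shape, SOURCE_MISSING, dtype=object)
        source[fixed_a | fixed_b] = SOURCE_FIXED
        source[poly] = SOURCE_LOGISTIC
        source[ambiguous] = SOURCE_AMBIGUOUS

        rows_f.append(freq)
        rows_s.append(source)
        used_snps.append(snp)
        if emit_calls:
            call = np.full(obs.shape, fx.MISSING, dtype=object)
            call[fixed_a] = fx.FIXED_A
            call[fixed_b] = fx.FIXED_B
            call[poly] = fx.POLYMORPHIC
            call[ambiguous] = fx.AMBIGUOUS
            for j, sample in enumerate(samples):
                call_rows.append((snp, sample, call[j], t_a[j], p_a[j],
                                  t_b[j], p_b[j]))

    if n_skipped:
        logger.warning("skipped %d kept SNPs lacking usable cluster statistics",
                       n_skipped)
    if not used_snps:
        raise ValueError("no SNP had both bulk FIR and cluster statistics")
    fm = FrequencyMatrix(
        pd.DataFrame(np.vstack(rows_f), index=used_snps, columns=samples),
        pd.DataFrame(np.vstack(rows_s), index=used_snps, columns=samples),
    )
    if emit_calls:
        calls = pd.DataFrame(call_rows, columns=[
            "snp_id", "population_id", "call", "t_A", "p_A", "t_B", "p_B"])
        return fm, calls
    return fm


def fixation_calls_table(fir_bulks: FIRMatrix,
                         cluster_stats: Iterable[ClusterStats],
                         fit: CalibrationFit,
                         kept_snps: Iterable[str],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-(SNP, bulk) fixation calls with both test statistics."""
    _, calls = estimate_frequencies(fir_bulks, cluster_stats, fit, kept_snps,
                                    alpha, emit_calls=True)
    return calls
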