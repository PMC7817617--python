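"""Synthetic inbred panels, controlled pools and landrace bulks.

The forward signal model is the inverse of the calibration curve: a bulk
with allele-B frequency 0 < f < 1 produces

    FIR = (logit(f) - alpha0) / beta0 + Normal(0, noise_sd),  clipped to [0, 1]

while a fixed bulk (f exactly 0 or 1) lands on the corresponding
homozygous cluster mean (mu_aa or mu_bb) plus the same noise — a fixed
pool is physically identical to a homozygous line, which is exactly what
the fixation test assumes of real arrays.  Under the defaults the curve
and the anchors meet smoothly: FIR(f) crosses mu_aa = 0.08 at
f = expit(-5 + 10*0.08) ~ 0.015, below the smallest realised bulk
frequency (1 of 30 gametes ~ 0.033) and close to the smallest controlled
pool (1%).

Reference-panel FIR values are drawn per homozygote cluster from
truncated Gaussians whose per-SNP means jitter slightly around the global
cluster anchors, producing a realistic spread of wd quality scores.
All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .calibration import (PoolDesign, classify_configuration,
                          expected_pool_frequency, standard_pool_designs)
from .io import FIRMatrix, FrequencyMatrix, GenotypeCallMatrix

__all__ = [
    "SignalModel",
    "SyntheticWorld",
    "fir_from_freq",
    "simulate_inbred_panel",
    "simulate_controlled_pools",
    "simulate_landrace_bulk",
    "make_world",
]


@dataclass(frozen=True)
class SignalModel:
    """Parameters of the forward FIR signal model.

    mu_aa/sd_aa and mu_bb/sd_bb describe the homozygote FIR clusters;
    alpha0/beta0 the true calibration curve; noise_sd the bulk FIR
    measurement noise; mean_jitter_sd the per-SNP jitter of cluster means
    (set it to 0 for an exactly noise-free world).
    """

    mu_aa: float = 0.08
    sd_aa: float = 0.02
    mu_bb: float = 0.92
    sd_bb: float = 0.02
    alpha0: float = -5.0
    beta0: float = 10.0
    noise_sd: float = 0.02
    mean_jitter_sd: float = 0.01

    def __post_init__(self) -> None:
        if not (self.mu_aa < self.mu_bb):
            raise ValueError("mu_aa must be below mu_bb")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        for sd in (self.sd_aa, self.sd_bb, self.noise_sd, self.mean_jitter_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")

    @property
    def f_lo(self) -> float:
        """Frequency whose noise-free FIR equals mu_aa (curve/anchor meet)."""
        return float(expit(self.alpha0 + self.beta0 * self.mu_aa))

    @property
    def f_hi(self) -> float:
        """Frequency whose noise-free FIR equals mu_bb (curve/anchor meet)."""
        return float(expit(self.alpha0 + self.beta0 * self.mu_bb))


@dataclass
class SyntheticWorld:
    """A fully known simulated study: ground truth plus every observable."""

    model: SignalModel
    true_pop_freqs: pd.DataFrame       # population-level truth, SNP x pop
    sampled_freqs: FrequencyMatrix     # realised bulk truth after gamete sampling
    fir_bulks: FIRMatrix
    panel_calls: GenotypeCallMatrix
    panel_fir: FIRMatrix
    pool_designs: list[PoolDesign]
    parent_genotypes: dict[str, pd.DataFrame]  # series -> SNP x 3 dosages
    pool_fir: FIRMatrix
    pool_expected: pd.DataFrame
    pool_classes: pd.DataFrame         # SNP x series configuration labels
    pool_samples: list[str] = field(default_factory=list)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def fir_from_freq(freq, model: SignalModel,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Forward model: FIR observation(s) for allele-B frequency ``freq``.

    Polymorphic frequencies lie on the inverse calibration curve; exact
    0/1 frequencies are anchored at the homozygous cluster means.
    """
    f = np.atleast_1d(np.asarray(freq, dtype=float))
    fir = np.empty_like(f)
    poly = (f > 0.0) & (f < 1.0)
    fir[poly] = (logit(f[poly]) - model.alpha0) / model.beta0
    fir[f == 0.0] = model.mu_aa
    fir[f == 1.0] = model.mu_bb
    if model.noise_sd > 0:
        fir = fir + _rng(rng).normal(0.0, model.noise_sd, size=f.shape)
    fir = np.clip(fir, 0.0, 1.0)
    return fir if np.ndim(freq) else fir[0]


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: float,
                      size: tuple[int, ...]) -> np.ndarray:
    # resampling would bias cluster means; plain clipping at [0, 1] is
    # negligible for default parameters (>4 sd from either boundary)
    if sd == 0:
        return np.broadcast_to(mean, size).copy()
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 1.0)


def simulate_inbred_panel(
    n_snps: int,
    n_lines: int,
    model: SignalModel | None = None,
    maf_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeCallMatrix, FIRMatrix]:
    """Simulate a homozygous reference panel and its FIR observations.

    Per SNP, each line is BB with probability equal to the SNP's B-allele
    frequency (drawn from ``maf_distribution``; default Uniform(0.05, 0.5))
    and AA otherwise — inbred lines carry no heterozygotes.  FIR values are
    Gaussian around per-SNP jittered cluster means.
    """
    if n_lines < 2:
        raise ValueError("need at least two reference lines")
    model = model or SignalModel()
    rng = _rng(rng)
    snps = [f"SNP{i:06d}" for i in range(n_snps)]
    lines = [f"L{j:04d}" for j in range(n_lines)]

    if maf_distribution is None:
        freq_b = rng.uniform(0.05, 0.5, size=n_snps)
    else:
        freq_b = np.asarray(maf_distribution(rng, n_snps), dtype=float)
    is_bb = rng.random((n_snps, n_lines)) < freq_b[:, None]

    mu_aa = model.mu_aa + (rng.normal(0.0, model.mean_jitter_sd, n_snps)
                           if model.mean_jitter_sd > 0 else 0.0)
    mu_bb = model.mu_bb + (rng.normal(0.0, model.mean_jitter_sd, n_snps)
                           if model.mean_jitter_sd > 0 else 0.0)
    mu_aa = np.broadcast_to(np.clip(mu_aa, 0.0, 1.0), (n_snps,))
    mu_bb = np.broadcast_to(np.clip(mu_bb, 0.0, 1.0), (n_snps,))

    fir_aa = _truncated_normal(rng, np.repeat(mu_aa[:, None], n_lines, axis=1),
                               model.sd_aa, (n_snps, n_lines))
    fir_bb = _truncated_normal(rng, np.repeat(mu_bb[:, None], n_lines, axis=1),
                               model.sd_bb, (n_snps, n_lines))
    fir = np.where(is_bb, fir_bb, fir_aa)
    calls = np.where(is_bb, "BB", "AA").astype(object)

    return (GenotypeCallMatrix(pd.DataFrame(calls, index=snps, columns=lines)),
            FIRMatrix(pd.DataFrame(fir, index=snps, columns=lines)))


def simulate_controlled_pools(
    parent_genotypes: Mapping[str, pd.DataFrame],
    model: SignalModel | None = None,
    designs: Sequence[PoolDesign] | None = None,
    rng: np.random.Generator | int | None = None,
    include_parents: bool = True,
) -> tuple[FIRMatrix, pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate FIR for controlled pools (and optionally the parents).

    ``parent_genotypes`` maps a series id to a SNP x 3 dosage frame.
    Returns (pool FIR matrix, expected-frequency frame, per-series
    configuration-class frame, list of pool sample ids).  Parent samples
    are named ``<series>:L<i>`` and pools ``<series>:#<j>``.
    """
    model = model or SignalModel()
    rng = _rng(rng)
    series_ids = list(parent_genotypes)
    snps = list(parent_genotypes[series_ids[0]].index)

    fir_cols: dict[str, np.ndarray] = {}
    exp_cols: dict[str, np.ndarray] = {}
    classes = pd.DataFrame(index=snps, columns=series_ids, dtype=object)
    pool_sample_ids: list[str] = []

    for sid in series_ids:
        dos = parent_genotypes[sid].loc[snps].to_numpy(dtype=int)
        if dos.shape[1] != 3:
            raise ValueError("each series needs exactly three parents")
        classes[sid] = [classify_configuration(d) for d in dos]
        series_designs = (list(designs) if designs is not None
                          else standard_pool_designs(sid))
        for d in series_designs:
            name = f"{sid}:{d.pool_id}"
            props = np.asarray(d.proportions)
            exp = dos @ props
            exp_cols[name] = exp
            fir_cols[name] = fir_from_freq(exp, model, rng)
            pool_sample_ids.append(name)
        if include_parents:
            for j in range(3):
                name = f"{sid}:L{j + 1}"
                exp = dos[:, j].astype(float)
                exp_cols[name] = exp
                fir_cols[name] = fir_from_freq(exp, model, rng)

    fir = FIRMatrix(pd.DataFrame(fir_cols, index=snps))
    expected = pd.DataFrame(exp_cols, index=snps)
    return fir, expected, classes, pool_sample_ids


def simulate_landrace_bulk(
    true_pop_freqs: Sequence[float],
    n_individuals: int = 15,
    model: SignalModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one bulk of ``n_individuals`` plants from a population.

    Gamete sampling: the realised bulk frequency at each SNP is
    Binomial(2n, f)/2n; the FIR observation then follows the forward
    signal model applied to that realised frequency.
    """
    f = np.asarray(true_pop_freqs, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("population frequencies must lie in [0, 1]")
    rng = _rng(rng)
    n_gametes = 2 * n_individuals
    sampled = rng.binomial(n_gametes, f) / n_gametes
    fir = fir_from_freq(sampled, model or SignalModel(), rng)
    return sampled, fir


def _default_pop_freqs(rng: np.random.Generator, n_snps: int, n_pops: int,
                       p_fixed: float = 0.5) -> np.ndarray:
    """Per-SNP, per-population truth: fixed with probability ``p_fixed``
    (allele chosen fairly), otherwise Beta(2, 2)-distributed.

    Roughly half the loci fixed per population matches what pooled
    genotyping of landraces shows; the mound-shaped Beta(2, 2) spectrum
    reflects array SNPs ascertained for intermediate diversity.
    """
    freqs = rng.beta(2.0, 2.0, size=(n_snps, n_pops))
    fixed = rng.random((n_snps, n_pops)) < p_fixed
    fixed_allele = (rng.random((n_snps, n_pops)) < 0.5).astype(float)
    return np.where(fixed, fixed_allele, freqs)


def make_world(n_snps: int = 2000, n_lines: int = 120, n_pops: int = 8,
               n_individuals: int = 15, model: SignalModel | None = None,
               seed: int | None = 0, n_replicated_pops: int = 0,
               p_fixed: float = 0.5,
               maf_distribution: Callable[[np.random.Generator, int],
                                          np.ndarray] | None = None
               ) -> SyntheticWorld:
    """Build a complete synthetic study from one seed.

    Emits a reference inbred panel, two series of controlled pools with
    their parents, and ``n_pops`` landrace bulks (the first
    ``n_replicated_pops`` populations get two independent bulks, named
    ``<pop>_rep1``/``<pop>_rep2``).
    """
    model = model or SignalModel()
    rng = _rng(seed)
    panel_calls, panel_fir = simulate_inbred_panel(n_snps, n_lines, model,
                                                   maf_distribution, rng)
    snps = panel_calls.snp_ids

    parent_genotypes = {
        sid: pd.DataFrame(rng.integers(0, 2, size=(n_snps, 3)),
                          index=snps, columns=["L1", "L2", "L3"])
        for sid in ("S1", "S2")
    }
    pool_fir, pool_expected, pool_classes, pool_samples = \
        simulate_controlled_pools(parent_genotypes, model, rng=rng)
    designs = (standard_pool_designs("S1") + standard_pool_designs("S2"))

    truth = _default_pop_freqs(rng, n_snps, n_pops, p_fixed)
    pop_ids = [f"POP{k:03d}" for k in range(n_pops)]
    true_pop = pd.DataFrame(truth, index=snps, columns=pop_ids)

    bulk_cols: dict[str, np.ndarray] = {}
    sampled_cols: dict[str, np.ndarray] = {}
    for k, pop in enumerate(pop_ids):
        n_bulks = 2 if k < n_replicated_pops else 1
        for b in range(n_bulks):
            name = f"{pop}_rep{b + 1}" if n_bulks == 2 else pop
            sampled, fir = simulate_landrace_bulk(truth[:, k], n_individuals,
                                                  model, rng)
            sampled_cols[name] = sampled
            bulk_cols[name] = fir

    sampled_freqs = FrequencyMatrix(pd.DataFrame(sampled_cols, index=snps))
    fir_bulks = FIRMatrix(pd.DataFrame(bulk_cols, index=snps))
    return SyntheticWorld(model, true_pop, sampled_freqs, fir_bulks,
                          panel_calls, panel_fir, designs, parent_genotypes,
                          pool_fir, pool_expected, pool_classes, pool_samples)
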