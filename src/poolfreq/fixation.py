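"""Step 1 of the two-step estimator: allele-fixation testing.

A DNA bulk truly fixed for allele A should have a FIR indistinguishable
from the reference AA homozygote cluster.  Each bulk FIR is therefore
tested for membership of the AA and of the BB cluster with a two-sided
single-observation Student test: under the Gaussian cluster model a new
observation satisfies

    (obs - mu_hat) / (sd_hat * sqrt(1 + 1/n))  ~  t(n - 1),

the prediction-interval form that accounts for the estimation error of the
cluster mean.  Member of exactly one cluster -> fixed for that allele;
member of neither -> polymorphic (handed to the calibration curve);
member of both (overlapping clusters) -> ambiguous, reported as missing
downstream rather than silently resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _st

from .quality import ClusterStats

__all__ = [
    "FIXED_A",
    "FIXED_B",
    "POLYMORPHIC",
    "AMBIGUOUS",
    "MISSING",
    "MembershipResult",
    "FixationResult",
    "membership_test",
    "classify_fixation",
]

FIXED_A = "FIXED_A"
FIXED_B = "FIXED_B"
POLYMORPHIC = "POLYMORPHIC"
AMBIGUOUS = "AMBIGUOUS"
MISSING = "MISSING"


@dataclass(frozen=True)
class MembershipResult:
    t: float
    p: float
    member: bool


@dataclass(frozen=True)
class FixationResult:
    call: str
    t_a: float
    p_a: float
    t_b: float
    p_b: float
    snp_id: str | None = None
    population_id: str | None = None


def membership_test(fir_obs: float, mu: float, sd: float, n: int,
                    alpha: float = 0.05) -> MembershipResult:
    """Test whether one FIR observation belongs to a Gaussian cluster.

    Membership is retained when the two-sided p-value is >= ``alpha``.
    A degenerate cluster (sd == 0) admits only an exact match.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0 or math.isnan(sd):
        member = fir_obs == mu
        return MembershipResult(0.0 if member else math.inf,
                                1.0 if member else 0.0, member)
    if n < 2:
        raise ValueError("membership test needs n >= 2 cluster members")
    t = (fir_obs - mu) / (sd * math.sqrt(1.0 + 1.0 / n))
    p = 2.0 * float(_st.t.sf(abs(t), n - 1))
    return MembershipResult(t, p, p >= alpha)


def classify_fixation(fir_obs: float, cs: ClusterStats, alpha: float = 0.05,
                      snp_id: str | None = None,
                      population_id: str | None = None) -> FixationResult:
    """Classify one bulk at one SNP as fixed-A, fixed-B, polymorphic or
    ambiguous from its FIR and the reference cluster statistics.

    For a cluster absent from the reference panel the theoretical
    homozygote mean is substituted (0 for the AA side, 1 for the BB side)
    with the observed cluster's spread and degrees of freedom, mirroring
    the monomorphic-SNP rule of the wd score.
    """
    if fir_obs is None or (isinstance(fir_obs, float) and math.isnan(fir_obs)):
        return FixationResult(MISSING, math.nan, math.nan, math.nan, math.nan,
                              snp_id, population_id)

    mu_a, sd_a, n_a = cs.mu_aa, cs.sd_aa, cs.n_aa
    mu_b, sd_b, n_b = cs.mu_bb, cs.sd_bb, cs.n_bb
    if n_a == 0:
        mu_a, sd_a, n_a = 0.0, cs.sd_bb, cs.n_bb
    if n_b == 0:
        mu_b, sd_b, n_b = 1.0, cs.sd_aa, cs.n_aa
    if n_a == 0 and n_b == 0:
        raise ValueError(f"no reference cluster for SNP {cs.snp_id!r}")
    # single-member clusters have no spread estimate -> degenerate sd-0 rule
    if n_a == 1:
        sd_a = 0.0
    if n_b == 1:
        sd_b = 0.0

    res_a = membership_test(fir_obs, mu_a, sd_a, n_a, alpha)
    res_b = membership_test(fir_obs, mu_b, sd_b, n_b, alpha)

    if res_a.member and res_b.member:
        call = AMBIGUOUS
    elif res_a.member:
        call = FIXED_A
    elif res_b.member:
        call = FIXED_B
    else:
        call = POLYMORPHIC
    return FixationResult(call, res_a.t, res_a.p, res_b.t, res_b.p,
                          snp_id, population_id)
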