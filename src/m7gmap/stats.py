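"""Log-likelihood-ratio tests on per-site mutation rates.

Two tests are provided. The between-group test compares a single shared
mutation frequency for pooled treated + control reads (H0) against separate
frequencies per condition (H1), with 1 degree of freedom. The within-group
test checks replicate consistency: one shared frequency across the k
replicates of a condition (H0) against one frequency per replicate (H1),
with k - 1 degrees of freedom. Both statistics are 2(l1 - l0) referred to a
chi-square upper tail, and both rest on the error-aware mixture likelihood of
:mod:`m7gmap.error_model` — with error-free observations they reduce exactly
to the classical binomial LRTs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import chi2

from .error_model import ObservationSet, estimate_rate_em

__all__ = [
    "GroupData",
    "TestResult",
    "lrt_between",
    "lrt_within",
    "mutation_rate_difference",
    "P_FLOOR",
    "NEG10LOG10_CAP",
]

#: p-values are floored here to keep -10*log10(p) printable; the calling
#: thresholds of interest (1e-50) are far above this.
P_FLOOR = 1e-320
NEG10LOG10_CAP = 3200.0


@dataclass
class GroupData:
    """Replicate observation sets for one condition (treated or control)."""

    replicates: list[ObservationSet]

    def pooled(self) -> ObservationSet:
        return ObservationSet.pooled(self.replicates)

    @property
    def n_obs(self) -> int:
        return sum(r.n_obs for r in self.replicates)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    neg10log10_p: float


def _finish(stat: float, df: int) -> TestResult:
    # tiny negative statistics are numerical noise from EM tolerance
    stat = 0.0 if stat < 0.0 else stat
    p = float(chi2.sf(stat, df))
    p = max(p, P_FLOOR)
    return TestResult(stat, df, p, min(-10.0 * math.log10(p), NEG10LOG10_CAP))


def lrt_between(treated: GroupData, control: GroupData) -> Optional[TestResult]:
    """Treated-vs-control rate-difference LRT (df = 1).

    Replicates within a condition are pooled (the ML fit under a shared
    per-condition frequency). Returns ``None`` when either condition has no
    observations — the position is untestable, not significant.
    """
    t_pool = treated.pooled()
    c_pool = control.pooled()
    if t_pool.n_obs == 0 or c_pool.n_obs == 0:
        return None
    ll_t = estimate_rate_em(t_pool).log_likelihood
    ll_c = estimate_rate_em(c_pool).log_likelihood
    ll_0 = estimate_rate_em(ObservationSet.pooled([t_pool, c_pool])).log_likelihood
    return _finish(2.0 * (ll_t + ll_c - ll_0), 1)


def lrt_within(group: GroupData) -> Optional[TestResult]:
    """Replicate-heterogeneity LRT within one condition (df = k - 1).

    Replicates without observations carry no information and are excluded;
    returns ``None`` with fewer than two informative replicates.
    """
    reps = [r for r in group.replicates if r.n_obs > 0]
    k = len(reps)
    if k < 2:
        return None
    ll_1 = sum(estimate_rate_em(r).log_likelihood for r in reps)
    ll_0 = estimate_rate_em(ObservationSet.pooled(reps)).log_likelihood
    return _finish(2.0 * (ll_1 - ll_0), k - 1)


def mutation_rate_difference(f_treated: float, f_control: float) -> float:
    """Primary effect size: treated minus control estimated mutation frequency."""
    for name, f in (("f_treated", f_treated), ("f_control", f_control)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}={f} outside [0, 1]")
    return f_treated - f_control
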