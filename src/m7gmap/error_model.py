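"""Error-aware maximum-likelihood estimation of per-site mutation frequencies.

Each aligned read base at a site is a draw from a two-class mixture: the read
came from a mutated template (probability ``f``, the quantity of interest) or
from a reference template (probability ``1 - f``). The per-read sequencing /
alignment error probability ``e`` (from the Phred quality, after BAQ upstream)
sets the emission probabilities:

========================  =====================  =====================
observation               P(obs | reference)     P(obs | mutated)
========================  =====================  =====================
reference match           ``1 - e``              ``e / 3``
substitution              ``e``                  ``1 - e/3``
insertion / deletion      ``e``                  ``1 - e``
========================  =====================  =====================

The ``e/3`` factor is the uniform-miscall convention for a 4-letter channel;
indels sit outside that channel, so no ``/3`` applies. ``f`` is fitted by EM
(E-step: posterior mutated-template weight per read; M-step: the mean weight),
a concave 1-D problem where the log-likelihood is non-decreasing per step.
With all ``e = 0`` the estimate is exactly the mutated-read fraction ``k/n``.

Observations are stored run-length compressed over unique (class, quality)
pairs; all computations are count-weighted, which is identical to the
per-read formulation because reads are exchangeable given class and ``e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .pileup_io import DELETION, INSERTION, MATCH, SUBSTITUTION, Observation

__all__ = [
    "ERROR_CAP",
    "phred_to_error",
    "phred_code_to_error",
    "ObservationSet",
    "RateEstimate",
    "site_log_likelihood",
    "em_step",
    "estimate_rate_em",
]

#: Error probabilities above this are clamped, keeping the two mixture
#: classes identifiable (at e = 0.75 match and mutated emissions coincide).
ERROR_CAP = 0.75

_PHRED_ERR = np.minimum(
    10.0 ** (-(np.arange(256, dtype=float) - 33.0) / 10.0), ERROR_CAP
)


def phred_code_to_error(code: int) -> float:
    """Error probability for a raw Phred+33 ASCII code, capped at 0.75."""
    if not 33 <= code <= 126:
        raise ValueError(f"Phred+33 code {code} outside printable range [33, 126]")
    return float(_PHRED_ERR[code])


def phred_to_error(quality_char: str) -> float:
    """Error probability ``10**(-Q/10)`` for a Phred+33 quality character."""
    return phred_code_to_error(ord(quality_char))


# model classes: match / substitution / indel (insertion and deletion share
# emission probabilities)
_CLS_MATCH = 0
_CLS_SUB = 1
_CLS_INDEL = 2

_KIND_TO_CLS = np.zeros(256, dtype=np.uint8)
_KIND_TO_CLS[MATCH] = _CLS_MATCH
_KIND_TO_CLS[SUBSTITUTION] = _CLS_SUB
_KIND_TO_CLS[INSERTION] = _CLS_INDEL
_KIND_TO_CLS[DELETION] = _CLS_INDEL


def _emissions(cls: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_ref = np.where(cls == _CLS_MATCH, 1.0 - e, e)
    p_mut = np.select(
        [cls == _CLS_MATCH, cls == _CLS_SUB], [e / 3.0, 1.0 - e / 3.0], 1.0 - e
    )
    return p_ref, p_mut


@dataclass(frozen=True)
class ObservationSet:
    """Compressed per-site observations for one sample or pooled samples.

    ``p_ref``/``p_mut`` are the emission probabilities of each distinct
    observation class, ``counts`` how many reads fall in it, ``mutated``
    whether the class is a non-reference observation.
    """

    p_ref: np.ndarray
    p_mut: np.ndarray
    counts: np.ndarray
    mutated: np.ndarray

    @property
    def n_obs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_mutated(self) -> int:
        return int(self.counts[self.mutated].sum())

    @classmethod
    def empty(cls) -> "ObservationSet":
        z = np.empty(0)
        return cls(z, z, np.empty(0, dtype=np.int64), np.empty(0, dtype=bool))

    @classmethod
    def from_arrays(cls, kinds: np.ndarray, qcodes: np.ndarray) -> "ObservationSet":
        """Build from parallel kind / Phred+33-code arrays (tokenizer output)."""
        if len(kinds) == 0:
            return cls.empty()
        mcls = _KIND_TO_CLS[kinds]
        key = mcls.astype(np.int32) * 256 + qcodes
        uniq, counts = np.unique(key, return_counts=True)
        ucls = (uniq // 256).astype(np.uint8)
        e = _PHRED_ERR[uniq % 256]
        p_ref, p_mut = _emissions(ucls, e)
        return cls(p_ref, p_mut, counts, ucls != _CLS_MATCH)

    @classmethod
    def from_observations(cls, obs: Iterable[Observation]) -> "ObservationSet":
        obs = list(obs)
        if not obs:
            return cls.empty()
        mcls = np.array([_KIND_TO_CLS[o.kind] for o in obs], dtype=np.uint8)
        e = np.minimum(np.array([o.error_prob for o in obs]), ERROR_CAP)
        p_ref, p_mut = _emissions(mcls, e)
        return cls(p_ref, p_mut, np.ones(len(obs), dtype=np.int64), mcls != _CLS_MATCH)

    @classmethod
    def from_counts(
        cls,
        n_mutated: int,
        n_total: int,
        error_prob: float,
        kind: str = "substitution",
    ) -> "ObservationSet":
        """Uniform-quality set with ``n_mutated`` non-reference reads of one kind."""
        if not 0 <= n_mutated <= n_total:
            raise ValueError("need 0 <= n_mutated <= n_total")
        e = min(float(error_prob), ERROR_CAP)
        mut_cls = _CLS_INDEL if kind in ("insertion", "deletion", "indel") else _CLS_SUB
        mcls = np.array([_CLS_MATCH, mut_cls], dtype=np.uint8)
        p_ref, p_mut = _emissions(mcls, np.array([e, e]))
        counts = np.array([n_total - n_mutated, n_mutated], dtype=np.int64)
        keep = counts > 0
        return cls(p_ref[keep], p_mut[keep], counts[keep], (mcls != _CLS_MATCH)[keep])

    @classmethod
    def pooled(cls, sets: Sequence["ObservationSet"]) -> "ObservationSet":
        sets = [s for s in sets if s.n_obs > 0]
        if not sets:
            return cls.empty()
        return cls(
            np.concatenate([s.p_ref for s in sets]),
            np.concatenate([s.p_mut for s in sets]),
            np.concatenate([s.counts for s in sets]),
            np.concatenate([s.mutated for s in sets]),
        )


@dataclass(frozen=True)
class RateEstimate:
    """ML mutation frequency with convergence metadata.

    ``f_hat`` is NaN when the set was empty (depth 0): an undefined estimate,
    not an error.
    """

    f_hat: float
    log_likelihood: float
    n_obs: int
    iterations: int
    converged: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.f_hat)


def site_log_likelihood(f: float, obs: ObservationSet) -> float:
    """Mixture log-likelihood ``sum_i c_i log[f p_mut,i + (1-f) p_ref,i]``.

    Returns 0.0 for an empty set and ``-inf`` when some observed class is
    impossible at this ``f`` (e.g. an error-free mismatch at ``f = 0``).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency {f} outside [0, 1]")
    if obs.n_obs == 0:
        return 0.0
    lik = f * obs.p_mut + (1.0 - f) * obs.p_ref
    if np.any(lik <= 0.0):
        return float("-inf")
    return float(np.dot(obs.counts, np.log(lik)))


def em_step(f: float, obs: ObservationSet) -> float:
    """One EM update: posterior mutated-template weights, then their mean."""
    num = f * obs.p_mut
    denom = num + (1.0 - f) * obs.p_ref
    w = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0.0)
    return float(np.dot(obs.counts, w) / obs.counts.sum())


def estimate_rate_em(
    obs: ObservationSet, tol: float = 1e-8, max_iter: int = 200
) -> RateEstimate:
    """EM maximum-likelihood mutation frequency for one site and group.

    Initialized at the raw mutated fraction; iterates EM updates until the
    step change falls below ``tol``. Plain EM converges only linearly when
    the optimum sits at or near the ``f = 0`` boundary (clean control
    samples), so each pair of EM steps is followed by a guarded Aitken
    delta-squared extrapolation: the jump is kept only when it does not
    decrease the log-likelihood, preserving EM's monotone-ascent guarantee.
    """
    n = obs.n_obs
    if n == 0:
        return RateEstimate(float("nan"), float("nan"), 0, 0, False)
    f = obs.n_mutated / n
    converged = False
    it = 0
    while it < max_iter:
        f1 = em_step(f, obs)
        it += 1
        if abs(f1 - f) < tol:
            f = f1
            converged = True
            break
        f2 = em_step(f1, obs)
        it += 1
        if abs(f2 - f1) < tol:
            f = f2
            converged = True
            break
        d1, d2 = f1 - f, f2 - f1
        denom = d2 - d1
        f_next = f2
        if denom != 0.0:
            fa = min(max(f - d1 * d1 / denom, 0.0), 1.0)
            if site_log_likelihood(fa, obs) >= site_log_likelihood(f2, obs):
                f_next = fa
        f = f_next
    return RateEstimate(f, site_log_likelihood(f, obs), n, it, converged)
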