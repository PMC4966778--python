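"""Poisson likelihood-set classification of peak strandedness.

A MeDIP-Seq peak with ``y_total`` first-mate reads split into ``y_plus``
forward and ``y_minus`` reverse-complement alignments is assigned to one of
three classes — plus-stranded, minus-stranded, or both strands — by asking
whether a single integer Poisson rate λ is simultaneously plausible for
both strand counts.  Candidate rates run from ``min(y_plus, y_minus)`` to
``max(y_plus, y_minus)`` inclusive.  For each strand the likelihood set

    LS_α = {λ : l(λ) / l(Λ) ≥ α},   Λ = argmax_λ l(λ)

collects the rates whose likelihood ratio against the maximum-likelihood
rate is at least α (default 0.1).  A nonempty intersection of the two sets
means a shared rate is plausible and the peak is double-stranded; an empty
intersection assigns the peak to the strand with the larger count.

All arithmetic is carried out in log space (log-gamma for factorials);
likelihood ratios are compared as log differences against log α.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum, auto
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammaln

from .genomic_features import GenomicInterval

__all__ = [
    "StrandClass",
    "StrandedPeakCount",
    "LikelihoodSetResult",
    "poisson_log_pmf",
    "likelihood_set",
    "classify_peak",
]


class StrandClass(Enum):
    """Three-way strand assignment of a methylation peak."""

    PLUS = auto()
    MINUS = auto()
    BOTH = auto()
    UNCLASSIFIED = auto()


@dataclass(frozen=True)
class StrandedPeakCount:
    """First-mate read counts of one peak, split by alignment strand.

    ``theta`` is the descriptive plus-strand fraction ``y_plus / y_total``
    (``None`` when the peak holds no reads); it plays no role in the
    decision rule, which compares each strand count against a shared
    candidate rate directly.
    """

    peak_id: str
    y_plus: int
    y_minus: int
    interval: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.y_plus < 0 or self.y_minus < 0:
            raise ValueError("strand counts must be non-negative")

    @property
    def y_total(self) -> int:
        return self.y_plus + self.y_minus

    @property
    def theta(self) -> Optional[float]:
        if self.y_total == 0:
            return None
        return self.y_plus / self.y_total


@dataclass(frozen=True)
class LikelihoodSetResult:
    """Likelihood sets of both strands and the resulting classification."""

    candidate_lambdas: range
    alpha: float
    ls_plus: frozenset[int]
    ls_minus: frozenset[int]
    intersection: frozenset[int]
    strand_class: StrandClass
    low_depth_flag: bool = False


def poisson_log_pmf(y: int, lam: int) -> float:
    """Log probability of observing ``y`` events under ``Poisson(lam)``.

    The ``lam == 0`` boundary is exact: probability 1 for ``y == 0`` and 0
    (log-probability −inf) otherwise.
    """
    if y < 0 or lam < 0:
        raise ValueError("y and lam must be non-negative")
    if lam == 0:
        return 0.0 if y == 0 else -math.inf
    return y * math.log(lam) - lam - float(gammaln(y + 1))


def _log_pmf_vector(y: int, lams: np.ndarray) -> np.ndarray:
    out = np.empty(lams.shape, dtype=float)
    pos = lams > 0
    out[pos] = y * np.log(lams[pos]) - lams[pos] - float(gammaln(y + 1))
    out[~pos] = 0.0 if y == 0 else -np.inf
    return out


def _as_contiguous_range(candidate_lambdas: Iterable[int]) -> range:
    if isinstance(candidate_lambdas, range):
        if len(candidate_lambdas) == 0:
            raise ValueError("candidate lambda set is empty")
        if candidate_lambdas.step != 1:
            raise ValueError("candidate lambdas must be contiguous")
        if candidate_lambdas.start < 0:
            raise ValueError("candidate lambdas must be non-negative")
        return candidate_lambdas
    values = sorted(set(int(v) for v in candidate_lambdas))
    if not values:
        raise ValueError("candidate lambda set is empty")
    if values[0] < 0:
        raise ValueError("candidate lambdas must be non-negative")
    if values[-1] - values[0] + 1 != len(values):
        raise ValueError("candidate lambdas must be contiguous")
    return range(values[0], values[-1] + 1)


def likelihood_set(
    y: int, candidate_lambdas: Iterable[int], alpha: float
) -> set[int]:
    """Integer rates whose likelihood ratio against the MLE is ≥ alpha.

    The maximum-likelihood rate Λ is taken over the candidate set, so the
    ratio at Λ is exactly 1 and the observed count is always a member when
    it lies inside the candidates.  The result is a contiguous integer
    range because the Poisson likelihood is unimodal in λ.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    cand = _as_contiguous_range(candidate_lambdas)
    lams = np.arange(cand.start, cand.stop)
    logl = _log_pmf_vector(int(y), lams)
    best = logl.max()
    if not np.isfinite(best):
        # every candidate has zero likelihood (y > 0 over {0} only)
        return set()
    mask = logl - best >= math.log(alpha)
    return set(int(v) for v in lams[mask])


def classify_peak(
    counts: StrandedPeakCount, alpha: float = 0.1, min_depth: int = 0
) -> LikelihoodSetResult:
    """Classify one peak as plus-, minus- or double-stranded.

    Candidate rates are the integers from ``min(y_plus, y_minus)`` to
    ``max(y_plus, y_minus)``.  A peak whose likelihood sets intersect is
    double-stranded; otherwise it is assigned to the strand with the
    larger count (equal counts always intersect, so no tie branch
    exists).  Peaks with fewer than ``min_depth`` total reads — and the
    degenerate zero-read peak — are reported UNCLASSIFIED with
    ``low_depth_flag`` set; their likelihood sets are still computed.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    lo = min(counts.y_plus, counts.y_minus)
    hi = max(counts.y_plus, counts.y_minus)
    cand = range(lo, hi + 1)
    ls_plus = frozenset(likelihood_set(counts.y_plus, cand, alpha))
    ls_minus = frozenset(likelihood_set(counts.y_minus, cand, alpha))
    inter = ls_plus & ls_minus

    low_depth = counts.y_total < min_depth or counts.y_total == 0
    if low_depth:
        cls = StrandClass.UNCLASSIFIED
    elif inter:
        cls = StrandClass.BOTH
    elif counts.y_plus > counts.y_minus:
        cls = StrandClass.PLUS
    else:
        cls = StrandClass.MINUS

    return LikelihoodSetResult(
        candidate_lambdas=cand,
        alpha=alpha,
        ls_plus=ls_plus,
        ls_minus=ls_minus,
        intersection=inter,
        strand_class=cls,
        low_depth_flag=low_depth,
    )
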