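"""Hyperparameter calibration by modified binary searches.

MWE regularization is tuned against sparsity behaviour rather than
signal quality: ``mu_max`` is the coupling strength past which the
estimate loses sparsity and spreads over the cortex (the working value
is ``mu_max / 2``), and the sparsity fraction ``lambda`` is searched so
that a target number of source points is active per subject (3 for
unilateral stimuli, 6 for vertical-meridian stimuli).

Both searches operate on an injected ``count_fn`` mapping a parameter
value to a mean active count, so they can be exercised on stub solvers
and reused with any problem context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mwe import MWEResult

__all__ = [
    "SearchFailure",
    "SearchResult",
    "count_active",
    "find_mu_max",
    "find_lambda",
]


class SearchFailure(RuntimeError):
    """Search could not be completed; carries the evaluation trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class SearchResult:
    """Outcome of one modified binary search."""

    parameter: str
    value: float
    recommended: float
    trace: list[tuple[float, float]] = field(default_factory=list)
    brackets: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True

    def trace_csv(self) -> str:
        lines = [f"{self.parameter},active_count"]
        lines += [f"{p:.10g},{c:.10g}" for p, c in self.trace]
        return "\n".join(lines) + "\n"


def count_active(
    solution: MWEResult | list[np.ndarray],
    rel_threshold: float = 1e-6,
) -> float:
    """Mean active source count per subject.

    A vertex is active when its magnitude exceeds ``rel_threshold``
    times the subject's maximum magnitude; an all-zero estimate counts
    zero.  Returns the mean over subjects.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    if isinstance(solution, MWEResult):
        vectors = [e.data for e in solution.estimates]
    else:
        vectors = [np.asarray(v, dtype=float) for v in solution]
    counts = []
    for x in vectors:
        m = np.max(np.abs(x)) if x.size else 0.0
        counts.append(0 if m == 0 else int(np.sum(np.abs(x) > rel_threshold * m)))
    return float(np.mean(counts))


def find_mu_max(
    count_fn: Callable[[float], float],
    mu_lo: float,
    mu_hi: float,
    target_active: float,
    spread_factor: float = 5.0,
    tol: float = 0.05,
    max_expand: int = 30,
) -> SearchResult:
    """Locate the sparsity-loss transition of the coupling strength mu.

    The estimate "loses sparsity" when the mean active count exceeds
    ``target_active * spread_factor``.  The upper bracket is expanded
    geometrically until it is past the transition, then a binary search
    on the log scale shrinks the bracket to relative width ``tol``.
    Returns the bracket midpoint as ``mu_max`` with the working value
    ``mu_max / 2`` in ``recommended``.
    """
    if mu_lo <= 0 or mu_hi <= mu_lo:
        raise ValueError("need 0 < mu_lo < mu_hi")
    threshold = target_active * spread_factor
    trace: list[tuple[float, float]] = []

    def count(mu: float) -> float:
        c = float(count_fn(mu))
        trace.append((mu, c))
        return c

    if count(mu_lo) > threshold:
        raise SearchFailure(
            f"estimate is already non-sparse at mu_lo={mu_lo:g}", trace
        )
    hi = mu_hi
    expansions = 0
    while count(hi) <= threshold:
        hi *= 4.0
        expansions += 1
        if expansions > max_expand:
            raise SearchFailure(
                f"no sparsity transition found up to mu={hi:g}", trace
            )
    lo = mu_lo
    brackets = [(lo, hi)]
    while hi / lo > 1.0 + tol:
        mid = float(np.sqrt(lo * hi))
        if count(mid) <= threshold:
            lo = mid
        else:
            hi = mid
        brackets.append((lo, hi))
    value = float(np.sqrt(lo * hi))
    return SearchResult(
        parameter="mu_max",
        value=value,
        recommended=value / 2.0,
        trace=trace,
        brackets=brackets,
    )


def find_lambda(
    count_fn: Callable[[float], float],
    target_active: float,
    tol: float = 1e-3,
    count_slack: float = 1.0,
    monotone_slack: float = 2.0,
) -> SearchResult:
    """Binary search for the lambda fraction hitting a target active count.

    Searches ``lambda in [0, 1]`` for a mean active count within
    ``count_slack`` of ``target_active``; the active count is assumed
    non-increasing in lambda, which is verified on the evaluation trace
    (violations beyond ``monotone_slack`` counts fail the search).
    """
    if target_active < 1:
        raise ValueError("target_active must be >= 1")
    trace: list[tuple[float, float]] = []

    def count(lam: float) -> float:
        c = float(count_fn(lam))
        trace.append((lam, c))
        return c

    def check_monotone() -> None:
        pts = sorted(trace)
        for (l1, c1), (l2, c2) in zip(pts, pts[1:]):
            if c2 > c1 + monotone_slack:
                raise SearchFailure(
                    f"active count not monotone in lambda: "
                    f"count({l1:g})={c1:g} < count({l2:g})={c2:g}",
                    trace,
                )

    c_hi = count(1.0)
    if abs(c_hi - target_active) <= count_slack:
        return SearchResult("lambda", 1.0, 1.0, trace, [(1.0, 1.0)])
    if c_hi > target_active:
        raise SearchFailure(
            f"active count at lambda=1 is {c_hi:g} > target {target_active:g}",
            trace,
        )
    lo, hi = 0.0, 1.0
    brackets = [(lo, hi)]
    value = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c = count(mid)
        if abs(c - target_active) <= count_slack:
            value = mid
            break
        if c > target_active:
            lo = mid
        else:
            hi = mid
        brackets.append((lo, hi))
    check_monotone()
    if value is None:
        raise SearchFailure(
            f"no lambda with active count within {count_slack:g} of "
            f"{target_active:g} (bracket [{lo:g}, {hi:g}])",
            trace,
        )
    return SearchResult("lambda", value, value, trace, brackets)
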