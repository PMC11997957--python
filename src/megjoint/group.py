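"""Group combination of per-subject source estimates.

All simulated subjects live on the shared template vertex set, so the
study-style "morph to the template, then average" reduces to a direct
vertex-wise mean.  Sparse signed estimates are averaged on absolute
values to keep opposite dipole polarities from cancelling.  Subject
groups are nested prefixes of a fixed ordering that starts from the
most representative subject (the one whose median peak-target distance
is closest to the group median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sources import SourceEstimate

__all__ = [
    "SubjectOrdering",
    "average_estimates",
    "select_representative",
    "order_subjects",
    "build_groups",
]


def average_estimates(
    estimates: list[SourceEstimate],
    use_absolute: bool = False,
) -> SourceEstimate:
    """Vertex-wise arithmetic mean of source estimates.

    With ``use_absolute`` the mean is taken over magnitudes (the MWE
    path, where signed dipole moments would otherwise cancel).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    first = estimates[0]
    for e in estimates[1:]:
        if not np.array_equal(e.vertices, first.vertices):
            raise ValueError("estimates must share vertex ids")
        if (e.times is None) != (first.times is None) or (
            e.times is not None and not np.array_equal(e.times, first.times)
        ):
            raise ValueError("estimates must share the time axis")
    stack = np.stack(
        [np.abs(e.data) if use_absolute else e.data for e in estimates]
    )
    return SourceEstimate(
        stack.mean(axis=0),
        first.vertices,
        times=first.times,
        signed=(not use_absolute) and first.signed,
    )


def select_representative(
    per_subject_medians: list[tuple[int, float]],
) -> int:
    """Subject whose median peak-target distance is closest to the group median.

    Ties break toward the lower subject id.
    """
    if not per_subject_medians:
        raise ValueError("need at least one subject")
    values = np.array([m for _, m in per_subject_medians], dtype=float)
    group_median = float(np.median(values))
    best_id, best_gap = None, np.inf
    for sid, m in sorted(per_subject_medians):
        gap = abs(m - group_median)
        if gap < best_gap:
            best_id, best_gap = sid, gap
    return int(best_id)


@dataclass
class SubjectOrdering:
    """Fixed subject order: representative first, then ascending id."""

    representative: int
    order: list[int]

    def __post_init__(self) -> None:
        if self.order[0] != self.representative:
            raise ValueError("representative must come first")


def order_subjects(per_subject_medians: list[tuple[int, float]]) -> SubjectOrdering:
    rep = select_representative(per_subject_medians)
    rest = sorted(sid for sid, _ in per_subject_medians if sid != rep)
    return SubjectOrdering(representative=rep, order=[rep] + rest)


def build_groups(
    ordering: SubjectOrdering,
    sizes: tuple[int, ...] = (1, 5, 10, 15, 20),
) -> list[list[int]]:
    """Nested prefix groups of the subject ordering."""
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be non-decreasing")
    if sizes and max(sizes) > len(ordering.order):
        raise ValueError(
            f"group size {max(sizes)} exceeds {len(ordering.order)} subjects"
        )
    return [list(ordering.order[:k]) for k in sizes]
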