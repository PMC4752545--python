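"""Classify raw observer marks into lesion (LL) and non-lesion (NL) localizations.

A mark counts as a lesion localization when its Euclidean distance to the
nearest true lesion does not exceed the acceptance radius (20 pixels in the
motivating study); otherwise it is a non-lesion localization.  Distance
exactly equal to the radius counts as within ("within the acceptance radius"
is read inclusively, which also makes the boundary deterministic).  When one
mark lies within the radius of several lesions it is assigned to the nearest
one; exact distance ties are broken toward the lowest lesion id.

If several marks land on the same lesion, that lesion's LL rating is the
maximum of their ratings.  The remaining (surplus) marks are discarded by
default: a pop-up-rating interface yields one deliberate mark per perceived
nodule, and demoting surplus marks to NL would double-count perception
events.  The alternative ``demote_to_nl`` policy is available for sensitivity
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import (
    SENTINEL,
    Design,
    MarkRecord,
    ScoredDataset,
    TruthMismatchError,
    TruthSpec,
)


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of mark classification.

    acceptance_radius
        maximum mark-to-lesion Euclidean distance, in pixels, for a mark to
        count as a lesion localization (inclusive).
    surplus_policy
        what to do with lower-rated extra marks that hit an already-marked
        lesion: ``"discard"`` (default) or ``"demote_to_nl"``.
    """

    acceptance_radius: float = 20.0
    surplus_policy: str = "discard"

    def __post_init__(self) -> None:
        if not self.acceptance_radius > 0:
            raise ValueError("acceptance_radius must be > 0")
        if self.surplus_policy not in ("discard", "demote_to_nl"):
            raise ValueError(f"unknown surplus_policy {self.surplus_policy!r}")


def nearest_lesion(
    x: float, y: float, lesions
) -> tuple[int, float] | tuple[None, float]:
    """Return ``(position_index, distance)`` of the lesion nearest to (x, y).

    The index is the position of the lesion within the per-case list (ordered
    by lesion id), so ties on distance resolve to the lowest lesion id.
    Returns ``(None, inf)`` if the case has no lesions.
    """
    best: tuple[float, int] | None = None
    for pos, les in enumerate(lesions):
        d = math.hypot(x - les.x, y - les.y)
        if best is None or d < best[0]:
            best = (d, pos)
    if best is None:
        return None, math.inf
    return best[1], best[0]


def classify_marks(
    marks: list[MarkRecord],
    truth: TruthSpec,
    config: ScoringConfig | None = None,
    *,
    n_factor1: int | None = None,
    n_factor2: int | None = None,
    n_readers: int | None = None,
    rating_bounds: tuple[float, float] | None = (1.0, 10.0),
) -> ScoredDataset:
    """Score raw marks against a truth table and assemble a :class:`ScoredDataset`.

    Design dimensions default to one plus the largest index observed in
    ``marks``; pass them explicitly when trailing factor levels or readers
    might have produced no marks at all.  Every input mark ends up exactly
    once as an LL contributor, an NL, or a discarded surplus mark.
    """
    config = config or ScoringConfig()
    case_known = set(truth.case_ids)
    for m in marks:
        if m.case_id not in case_known:
            raise TruthMismatchError(f"mark on unknown case {m.case_id!r}")

    I1 = n_factor1 if n_factor1 is not None else 1 + max((m.factor1 for m in marks), default=0)
    I2 = n_factor2 if n_factor2 is not None else 1 + max((m.factor2 for m in marks), default=0)
    J = n_readers if n_readers is not None else 1 + max((m.reader for m in marks), default=0)

    design = Design.from_truth(truth, I1, I2, J)
    case_index = {c: k for k, c in enumerate(design.normal_ids + design.abnormal_ids)}
    abnormal_index = {c: a for a, c in enumerate(design.abnormal_ids)}
    K1, K2, L = design.n_normal, design.n_abnormal, design.max_lesions

    ll = np.full((I1, I2, J, K2, max(L, 1)), SENTINEL)
    nl_lists: dict[tuple, list[float]] = {}
    # per (cell, lesion) keep all candidate ratings; best becomes the LL
    candidates: dict[tuple, list[float]] = {}

    for m in marks:
        cell = (m.factor1, m.factor2, m.reader)
        pos, dist = nearest_lesion(m.x, m.y, truth.lesions_for(m.case_id))
        if pos is not None and dist <= config.acceptance_radius:
            candidates.setdefault(cell + (m.case_id, pos), []).append(m.rating)
        else:
            nl_lists.setdefault(cell + (case_index[m.case_id],), []).append(m.rating)

    for (i1, i2, j, case_id, pos), ratings in candidates.items():
        a = abnormal_index[case_id]
        ratings = sorted(ratings, reverse=True)
        ll[i1, i2, j, a, pos] = ratings[0]
        if config.surplus_policy == "demote_to_nl":
            for r in ratings[1:]:
                nl_lists.setdefault((i1, i2, j, case_index[case_id]), []).append(r)

    M = max((len(v) for v in nl_lists.values()), default=0)
    nl = np.full((I1, I2, J, K1 + K2, max(M, 1)), SENTINEL)
    for (i1, i2, j, k), ratings in nl_lists.items():
        nl[i1, i2, j, k, : len(ratings)] = sorted(ratings, reverse=True)

    weights = np.zeros((K2, max(L, 1)))
    for a, case_id in enumerate(design.abnormal_ids):
        lesions = truth.lesions_for(case_id)
        for pos, les in enumerate(lesions):
            weights[a, pos] = les.weight

    return ScoredDataset(
        nl=nl,
        ll=ll,
        lesion_weights=weights,
        case_ids=tuple(design.normal_ids + design.abnormal_ids),
        n_normal=K1,
        rating_bounds=rating_bounds,
    )
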