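"""Data model and CSV I/O for fully crossed factorial free-response (FROC) rating data.

A free-response observer study produces, for every combination of imaging
condition and reader, a set of marks per case: lesion localizations (LL,
marks close to a true lesion) and non-lesion localizations (NL, all other
marks).  Here the imaging condition is defined by two fully crossed factors —
in the motivating CT study, tube current–time product (mAs, 4 levels) and
image reconstruction method (2 levels) — so ratings live on a dense
``(factor1, factor2, reader, case, slot)`` grid.

Conventions
-----------
* Unmarked lesions and empty NL slots carry the sentinel ``-inf`` so that the
  rating-comparison kernel of the figures of merit treats marked and unmarked
  entities uniformly (an unmarked entity loses every strict comparison and
  ties another unmarked entity).
* Cases are indexed 0-based internally with normal cases first; CSV files
  carry the string case identifiers verbatim.
* Designs must be complete (fully crossed): every ``(factor1, factor2,
  reader)`` cell covers all cases.  Missing cells raise
  :class:`IncompleteDesignError` — the balanced-design ANOVA downstream does
  not support imputation.
* The 1–10 integer confidence scale of the motivating study is the default
  validation bound, not a hard limit; continuous ratings are accepted by
  setting ``rating_bounds`` (e.g. to ``None``) so that latent Gaussian
  ratings from the simulator can flow through the same pipeline.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Rating assigned to unmarked lesions / empty NL slots.  Strictly below any
#: legal rating, and equal only to itself.
SENTINEL = float("-inf")


class FrocError(Exception):
    """Base class for errors raised by this package."""


class IncompleteDesignError(FrocError):
    """The factorial design is not complete (a factor x reader cell is missing)."""


class TruthMismatchError(FrocError):
    """A mark or rating row references a case or lesion absent from the truth."""


class RatingValidationError(FrocError):
    """A rating violates the configured scale bounds."""


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lesion:
    """One true lesion: location in pixels, physical attributes and zone labels."""

    case_id: str
    lesion_id: int
    x: float
    y: float
    diameter_mm: float = 0.0
    density_hu: float = 0.0
    side: str = ""          # "right" / "left"
    level: str = ""         # "upper" / "mid" / "lower"
    depth: str = ""         # "anterior" / "posterior" / "central"
    peripheral: bool = False
    weight: float = 1.0


@dataclass(frozen=True)
class MarkRecord:
    """A raw observer mark: where it was placed and how confident the reader was."""

    factor1: int
    factor2: int
    reader: int
    case_id: str
    x: float
    y: float
    rating: float


@dataclass
class TruthSpec:
    """Gold standard for an observer study: the case set and the true lesions.

    Parameters
    ----------
    cases
        ``(case_id, is_abnormal)`` pairs.  Normal cases carry no lesions.
    lesions
        All true lesions.  Per-case lesion weights are expected to be equal
        and to sum to one (equal weighting gives every case the same
        importance regardless of its lesion count).
    """

    cases: list[tuple[str, bool]]
    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_case: dict[str, list[Lesion]] = {}
        for les in self.lesions:
            self._by_case.setdefault(les.case_id, []).append(les)
        for case_id in self._by_case:
            self._by_case[case_id].sort(key=lambda l: l.lesion_id)

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.cases]

    @property
    def normal_ids(self) -> list[str]:
        return [c for c, abn in self.cases if not abn]

    @property
    def abnormal_ids(self) -> list[str]:
        return [c for c, abn in self.cases if abn]

    def lesions_for(self, case_id: str) -> list[Lesion]:
        return self._by_case.get(case_id, [])

    def n_lesions(self, case_id: str) -> int:
        return len(self.lesions_for(case_id))

    @property
    def max_lesions(self) -> int:
        return max((len(v) for v in self._by_case.values()), default=0)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty iff the truth is valid)."""
        problems: list[str] = []
        known = set(self.case_ids)
        abnormal = set(self.abnormal_ids)
        if len(known) != len(self.cases):
            problems.append("duplicate case ids in truth table")
        for les in self.lesions:
            if les.case_id not in known:
                problems.append(f"lesion {les.lesion_id} on unknown case {les.case_id!r}")
            elif les.case_id not in abnormal:
                problems.append(f"lesion {les.lesion_id} on normal case {les.case_id!r}")
        for case_id in abnormal:
            lesions = self.lesions_for(case_id)
            if not lesions:
                problems.append(f"abnormal case {case_id!r} has no lesions")
                continue
            total = sum(l.weight for l in lesions)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                problems.append(
                    f"case {case_id!r}: lesion weights sum to {total:.6g}, expected 1"
                )
            if len({round(l.weight, 12) for l in lesions}) > 1:
                problems.append(f"case {case_id!r}: lesion weights are not equal")
        return problems


# ---------------------------------------------------------------------------
# Design description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Design:
    """Shape of a complete crossed-factor study: factor levels, readers, cases."""

    n_factor1: int
    n_factor2: int
    n_readers: int
    normal_ids: tuple[str, ...]
    abnormal_ids: tuple[str, ...]
    n_lesions: tuple[int, ...]  # per abnormal case, aligned with ``abnormal_ids``

    @classmethod
    def from_truth(
        cls, truth: TruthSpec, n_factor1: int, n_factor2: int, n_readers: int
    ) -> "Design":
        abnormal = tuple(truth.abnormal_ids)
        return cls(
            n_factor1=n_factor1,
            n_factor2=n_factor2,
            n_readers=n_readers,
            normal_ids=tuple(truth.normal_ids),
            abnormal_ids=abnormal,
            n_lesions=tuple(truth.n_lesions(c) for c in abnormal),
        )

    @property
    def n_normal(self) -> int:
        return len(self.normal_ids)

    @property
    def n_abnormal(self) -> int:
        return len(self.abnormal_ids)

    @property
    def max_lesions(self) -> int:
        return max(self.n_lesions, default=0)


# ---------------------------------------------------------------------------
# Dense rating container
# ---------------------------------------------------------------------------


@dataclass
class ScoredDataset:
    """Complete NL/LL rating arrays for a fully crossed factorial FROC study.

    Attributes
    ----------
    nl
        float array of shape ``(I1, I2, J, K, M)`` holding non-lesion
        localization ratings for every case (normals first); empty slots are
        ``-inf``.
    ll
        float array of shape ``(I1, I2, J, K2, L)`` holding lesion
        localization ratings for abnormal cases; unmarked lesions and
        nonexistent lesion slots are ``-inf``.
    lesion_weights
        float array ``(K2, L)``; zero marks a nonexistent lesion slot, and
        each row with lesions sums to one.
    case_ids
        string identifiers, normals first, length ``K = K1 + K2``.
    n_normal
        number of normal cases ``K1``.
    rating_bounds
        inclusive ``(lo, hi)`` bounds for finite ratings, or ``None`` to
        accept any finite rating.
    """

    nl: np.ndarray
    ll: np.ndarray
    lesion_weights: np.ndarray
    case_ids: tuple[str, ...]
    n_normal: int
    rating_bounds: tuple[float, float] | None = (1.0, 10.0)

    # -- shape accessors ----------------------------------------------------
    @property
    def n_factor1(self) -> int:
        return self.nl.shape[0]

    @property
    def n_factor2(self) -> int:
        return self.nl.shape[1]

    @property
    def n_readers(self) -> int:
        return self.nl.shape[2]

    @property
    def n_cases(self) -> int:
        return self.nl.shape[3]

    @property
    def n_abnormal(self) -> int:
        return self.ll.shape[3]

    @property
    def max_nl(self) -> int:
        return self.nl.shape[4]

    @property
    def max_lesions(self) -> int:
        return self.ll.shape[4]

    @property
    def normal_ids(self) -> tuple[str, ...]:
        return self.case_ids[: self.n_normal]

    @property
    def abnormal_ids(self) -> tuple[str, ...]:
        return self.case_ids[self.n_normal :]

    @property
    def n_lesions_per_case(self) -> np.ndarray:
        return (self.lesion_weights > 0).sum(axis=1)

    def validate(self) -> list[str]:
        """Check all structural invariants; returns violations, empty iff valid."""
        problems: list[str] = []
        I1, I2, J, K, _ = self.nl.shape
        if self.ll.shape[:3] != (I1, I2, J):
            problems.append("nl and ll disagree on design dimensions")
        if self.ll.shape[3] != K - self.n_normal:
            problems.append("ll case dimension does not match K - n_normal")
        if self.lesion_weights.shape != self.ll.shape[3:]:
            problems.append("lesion_weights shape does not match ll")
        if len(self.case_ids) != K:
            problems.append("case_ids length does not match nl case dimension")

        if self.rating_bounds is not None:
            lo, hi = self.rating_bounds
            for name, arr in (("NL", self.nl), ("LL", self.ll)):
                finite = arr[np.isfinite(arr)]
                n_bad = int(((finite < lo) | (finite > hi)).sum())
                if n_bad:
                    problems.append(
                        f"{n_bad} finite {name} rating(s) outside bounds [{lo}, {hi}]"
                    )

        # unmarked entities must carry the sentinel, never +inf or NaN
        for name, arr in (("NL", self.nl), ("LL", self.ll)):
            if np.isnan(arr).any() or np.isposinf(arr).any():
                problems.append(f"{name} ratings contain NaN or +inf")

        # finite LL ratings only on real lesion slots
        ghost = np.isfinite(self.ll) & (self.lesion_weights == 0)[None, None, None]
        if ghost.any():
            problems.append("finite LL rating on a nonexistent lesion slot")

        row_sums = self.lesion_weights.sum(axis=1)
        has_lesion = (self.lesion_weights > 0).any(axis=1)
        if not has_lesion.all():
            problems.append("abnormal case with no lesions")
        bad = has_lesion & ~np.isclose(row_sums, 1.0, atol=1e-9)
        for idx in np.nonzero(bad)[0]:
            problems.append(
                f"abnormal case {self.abnormal_ids[idx]!r}: lesion weights sum to "
                f"{row_sums[idx]:.6g}, expected 1"
            )
        if (self.lesion_weights < 0).any():
            problems.append("negative lesion weight")
        return problems


def validate(ds: ScoredDataset) -> list[str]:
    """Module-level alias for :meth:`ScoredDataset.validate`."""
    return ds.validate()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SCORED_COLUMNS = ["factor1", "factor2", "reader", "case", "type", "lesion", "rating"]
_TRUTH_COLUMNS = [
    "case", "abnormal", "lesion", "x", "y", "diameter_mm", "density_hu",
    "side", "level", "depth", "peripheral", "weight",
]


def write_scored_csv(ds: ScoredDataset, path) -> str:
    """Write a scored dataset to CSV; sentinel (unmarked) entries produce no rows."""
    rows = []
    I1, I2, J, K, M = ds.nl.shape
    for i1, i2, j in itertools.product(range(I1), range(I2), range(J)):
        for k in range(K):
            for m in range(M):
                r = ds.nl[i1, i2, j, k, m]
                if np.isfinite(r):
                    rows.append((i1, i2, j, ds.case_ids[k], "NL", "", r))
        for a in range(ds.n_abnormal):
            for l in range(ds.max_lesions):
                r = ds.ll[i1, i2, j, a, l]
                if np.isfinite(r):
                    rows.append((i1, i2, j, ds.abnormal_ids[a], "LL", l, r))
    df = pd.DataFrame(rows, columns=_SCORED_COLUMNS)
    df.to_csv(path, index=False)
    return str(path)


def read_scored_csv(
    path,
    design: Design,
    rating_bounds: tuple[float, float] | None = (1.0, 10.0),
) -> ScoredDataset:
    """Read a scored-ratings CSV into a validated :class:`ScoredDataset`.

    The CSV must contain the columns ``factor1,factor2,reader,case,type,
    lesion,rating`` with ``type`` in ``{NL, LL}`` and ``lesion`` empty for NL
    rows.  Absent marks are filled with the ``-inf`` sentinel.  Raises
    :class:`IncompleteDesignError` if any ``(factor1, factor2, reader)`` cell
    contributes no rows, :class:`TruthMismatchError` for unknown cases or
    lesion indices, and :class:`RatingValidationError` for out-of-bounds
    ratings.
    """
    df = pd.read_csv(path, dtype={"case": str, "type": str}, keep_default_na=False)
    missing_cols = [c for c in _SCORED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FrocError(f"scored CSV missing columns: {missing_cols}")

    I1, I2, J = design.n_factor1, design.n_factor2, design.n_readers
    K1, K2 = design.n_normal, design.n_abnormal
    case_ids = design.normal_ids + design.abnormal_ids
    case_index = {c: k for k, c in enumerate(case_ids)}
    abnormal_index = {c: a for a, c in enumerate(design.abnormal_ids)}

    seen_cells = set()
    nl_marks: dict[tuple, list[float]] = {}
    L = design.max_lesions
    ll = np.full((I1, I2, J, K2, max(L, 1)), SENTINEL)
    for row in df.itertuples(index=False):
        i1, i2, j = int(row.factor1), int(row.factor2), int(row.reader)
        if not (0 <= i1 < I1 and 0 <= i2 < I2 and 0 <= j < J):
            raise IncompleteDesignError(
                f"row indices ({i1},{i2},{j}) outside design {I1}x{I2}x{J}"
            )
        seen_cells.add((i1, i2, j))
        case = str(row.case)
        if case not in case_index:
            raise TruthMismatchError(f"unknown case {case!r} in scored CSV")
        rating = float(row.rating)
        if not np.isfinite(rating):
            raise RatingValidationError(f"non-finite rating on case {case!r}")
        if rating_bounds is not None and not (rating_bounds[0] <= rating <= rating_bounds[1]):
            raise RatingValidationError(
                f"rating {rating} outside bounds {rating_bounds} on case {case!r}"
            )
        kind = str(row.type).strip().upper()
        if kind == "NL":
            nl_marks.setdefault((i1, i2, j, case_index[case]), []).append(rating)
        elif kind == "LL":
            if case not in abnormal_index:
                raise TruthMismatchError(f"LL row on normal case {case!r}")
            a = abnormal_index[case]
            lesion = str(row.lesion).strip()
            if lesion == "":
                raise TruthMismatchError(f"LL row without lesion id on case {case!r}")
            l = int(float(lesion))
            if not (0 <= l < design.n_lesions[a]):
                raise TruthMismatchError(
                    f"case {case!r}: lesion index {l} not in truth "
                    f"(has {design.n_lesions[a]} lesions)"
                )
            # several LL rows on one lesion collapse to the highest rating
            ll[i1, i2, j, a, l] = max(ll[i1, i2, j, a, l], rating)
        else:
            raise FrocError(f"unknown mark type {kind!r}")

    missing = sorted(
        set(itertools.product(range(I1), range(I2), range(J))) - seen_cells
    )
    if missing:
        raise IncompleteDesignError(
            f"incomplete design: no rows for cells (factor1,factor2,reader) {missing}"
        )

    M = max((len(v) for v in nl_marks.values()), default=0)
    nl = np.full((I1, I2, J, K1 + K2, max(M, 1)), SENTINEL)
    for (i1, i2, j, k), ratings in nl_marks.items():
        nl[i1, i2, j, k, : len(ratings)] = sorted(ratings, reverse=True)

    weights = np.zeros((K2, max(L, 1)))
    for a, n in enumerate(design.n_lesions):
        if n:
            weights[a, :n] = 1.0 / n

    return ScoredDataset(
        nl=nl,
        ll=ll,
        lesion_weights=weights,
        case_ids=tuple(case_ids),
        n_normal=K1,
        rating_bounds=rating_bounds,
    )


def write_truth_csv(truth: TruthSpec, path) -> str:
    rows = []
    for case_id, abnormal in truth.cases:
        lesions = truth.lesions_for(case_id)
        if not lesions:
            rows.append((case_id, int(abnormal), "", "", "", "", "", "", "", "", "", ""))
        for les in lesions:
            rows.append(
                (case_id, int(abnormal), les.lesion_id, les.x, les.y,
                 les.diameter_mm, les.density_hu, les.side, les.level,
                 les.depth, int(les.peripheral), les.weight)
            )
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, index=False)
    return str(path)


def read_truth_csv(path) -> TruthSpec:
    df = pd.read_csv(path, dtype={"case": str}, keep_default_na=False)
    missing_cols = [c for c in _TRUTH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FrocError(f"truth CSV missing columns: {missing_cols}")
    cases: list[tuple[str, bool]] = []
    seen: set[str] = set()
    lesions: list[Lesion] = []
    for row in df.itertuples(index=False):
        case = str(row.case)
        abnormal = bool(int(row.abnormal))
        if case not in seen:
            seen.add(case)
            cases.append((case, abnormal))
        if str(row.lesion).strip() != "":
            lesions.append(
                Lesion(
                    case_id=case,
                    lesion_id=int(float(row.lesion)),
                    x=float(row.x),
                    y=float(row.y),
                    diameter_mm=float(row.diameter_mm) if str(row.diameter_mm) else 0.0,
                    density_hu=float(row.density_hu) if str(row.density_hu) else 0.0,
                    side=str(row.side),
                    level=str(row.level),
                    depth=str(row.depth),
                    peripheral=bool(int(row.peripheral)) if str(row.peripheral) else False,
                    weight=float(row.weight) if str(row.weight) else 1.0,
                )
            )
    return TruthSpec(cases=cases, lesions=lesions)
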