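"""Figures of merit for free-response data, with leave-one-case-out jackknife.

Two figures of merit are provided, computed independently for every
``(factor1, factor2, reader)`` cell of a :class:`~xfroc.dataset.ScoredDataset`:

* **wAFROC** (equally weighted JAFROC FOM, θ): the weighted empirical
  probability that a lesion's rating exceeds the highest rating on a normal
  case,

  .. math::

     \\theta = \\frac{1}{K_1 K_2} \\sum_{n=1}^{K_1} \\sum_{a=1}^{K_2}
               \\sum_{\\ell \\in a} W_{a\\ell}\\,
               \\psi\\bigl(\\mathrm{LL}_{a\\ell},\\ \\mathrm{FP}_n\\bigr),

  where FP_n is the highest NL rating on normal case *n* (sentinel if the
  case carries no marks) and the per-case lesion weights W sum to one, giving
  every case equal importance regardless of its lesion count.  θ ranges over
  [0, 1].

* **inferred ROC** (highest-rating AUC, A): the Wilcoxon statistic on the
  per-case highest rating (over all NL and LL marks), i.e. the empirical AUC
  of the ROC inferred from the free-response data.  For observers at or above
  chance A lies in [0.5, 1].

The comparison kernel ψ scores 1 for a win, 0.5 for a tie and 0 for a loss.
Two unmarked entities (both at the ``-inf`` sentinel) tie and score 0.5 — the
kernel of an empirical probability must be defined for every pair, and the
tie convention keeps an observer who marks nothing at θ = 0.5 rather than 0.

The jackknife removes one case at a time (normal or abnormal) and recomputes
the FOM, yielding pseudovalues ``Y_k = K·θ − (K−1)·θ_(k)`` used for the
covariance estimates of the significance-testing machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dataset import SENTINEL, FrocError, ScoredDataset

#: Recognised figure-of-merit identifiers.
FOM_TYPES = ("wafroc", "inferred_roc")


class UndefinedFomError(FrocError):
    """The FOM is undefined (no normal or no abnormal cases in the comparison set)."""


def psi(a, b):
    """Rating-comparison kernel: 1 if ``a > b``, 0.5 if ``a == b``, 0 if ``a < b``.

    Accepts scalars or arrays (broadcast); the ``-inf`` sentinel compares like
    any other value, so two unmarked entities tie at 0.5.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.where(a > b, 1.0, np.where(a == b, 0.5, 0.0))
    return float(out) if out.ndim == 0 else out


def _normalize_fom_type(fom_type: str) -> str:
    key = fom_type.lower().replace("-", "_")
    aliases = {"wafroc": "wafroc", "jafroc": "wafroc",
               "inferred_roc": "inferred_roc", "roc": "inferred_roc"}
    if key not in aliases:
        raise ValueError(f"unknown fom_type {fom_type!r}; expected one of {FOM_TYPES}")
    return aliases[key]


def _highest(ratings: np.ndarray, axis: int = -1) -> np.ndarray:
    """Highest rating along ``axis``; sentinel when the slot dimension is empty."""
    if ratings.shape[axis] == 0:
        shape = list(ratings.shape)
        del shape[axis]
        return np.full(shape, SENTINEL)
    return ratings.max(axis=axis)


def _wafroc_pair_matrix(
    nl_normal: np.ndarray, ll: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """C[a, n] = sum_l W[a,l] psi(LL[a,l], FP[n]); theta = C.sum()/(K1*K2)."""
    fp = _highest(nl_normal)  # (K1,)
    p = psi(ll[:, :, None], fp[None, None, :])  # (K2, L, K1)
    return np.einsum("al,aln->an", weights, p)


def _roc_pair_matrix(
    nl: np.ndarray, ll: np.ndarray, n_normal: int
) -> np.ndarray:
    """C[a, n] = psi(H_a, H_n) with H the per-case highest rating over all marks."""
    h_all = _highest(nl)  # (K,)
    h_normal = h_all[:n_normal]
    h_abnormal = np.maximum(h_all[n_normal:], _highest(ll))
    return psi(h_abnormal[:, None], h_normal[None, :])


def _cell_pair_matrix(ds: ScoredDataset, i1: int, i2: int, j: int, fom_type: str) -> np.ndarray:
    if fom_type == "wafroc":
        return _wafroc_pair_matrix(
            ds.nl[i1, i2, j, : ds.n_normal], ds.ll[i1, i2, j], ds.lesion_weights
        )
    return _roc_pair_matrix(ds.nl[i1, i2, j], ds.ll[i1, i2, j], ds.n_normal)


def wafroc_fom(nl_normal: np.ndarray, ll: np.ndarray, lesion_weights: np.ndarray) -> float:
    """Equally weighted JAFROC FOM for one design cell.

    Parameters
    ----------
    nl_normal
        ``(K1, M)`` NL ratings on the normal cases only (abnormal-case NLs do
        not enter this FOM — false positives come from normal cases).
    ll
        ``(K2, L)`` lesion-localization ratings, ``-inf`` for unmarked.
    lesion_weights
        ``(K2, L)`` per-lesion weights, each case's weights summing to one.
    """
    K1, K2 = nl_normal.shape[0], ll.shape[0]
    if K1 < 1 or K2 < 1:
        raise UndefinedFomError("wAFROC requires at least one normal and one abnormal case")
    return float(_wafroc_pair_matrix(nl_normal, ll, lesion_weights).sum() / (K1 * K2))


def inferred_roc_fom(nl: np.ndarray, ll: np.ndarray, n_normal: int) -> float:
    """Highest-rating inferred-ROC AUC (Wilcoxon statistic) for one design cell.

    ``nl`` covers all cases (normals first, ``(K, M)``); ``ll`` covers the
    abnormal cases.  The inferred ROC rating of a case is the highest rating
    of any mark on it, sentinel if unmarked.
    """
    K1, K2 = n_normal, nl.shape[0] - n_normal
    if K1 < 1 or K2 < 1:
        raise UndefinedFomError("ROC FOM requires at least one normal and one abnormal case")
    return float(_roc_pair_matrix(nl, ll, n_normal).sum() / (K1 * K2))


@dataclass
class FomMatrix:
    """θ values on the full (factor1, factor2, reader) grid, tagged by FOM type."""

    values: np.ndarray  # (I1, I2, J)
    fom_type: str

    @property
    def n_factor1(self) -> int:
        return self.values.shape[0]

    @property
    def n_factor2(self) -> int:
        return self.values.shape[1]

    @property
    def n_readers(self) -> int:
        return self.values.shape[2]


@dataclass
class JackknifeSet:
    """Leave-one-case-out FOMs and pseudovalues for every design cell.

    ``theta`` has shape ``(..., J)`` (``(I1, I2, J)`` for the crossed design)
    and ``loo`` appends a trailing case axis of length ``K = K1 + K2``;
    ``loo[..., k]`` is the FOM recomputed with case ``k`` removed (normals
    first).  Pseudovalues are ``Y_k = K·θ − (K−1)·θ_(k)``.
    """

    theta: np.ndarray
    loo: np.ndarray
    n_normal: int
    n_abnormal: int
    fom_type: str

    @property
    def n_cases(self) -> int:
        return self.n_normal + self.n_abnormal

    @property
    def pseudovalues(self) -> np.ndarray:
        K = self.n_cases
        return K * self.theta[..., None] - (K - 1) * self.loo


def fom_matrix(ds: ScoredDataset, fom_type: str = "wafroc") -> FomMatrix:
    """Compute the chosen FOM independently for every (factor1, factor2, reader) cell."""
    fom_type = _normalize_fom_type(fom_type)
    I1, I2, J = ds.n_factor1, ds.n_factor2, ds.n_readers
    K1, K2 = ds.n_normal, ds.n_abnormal
    if K1 < 1 or K2 < 1:
        raise UndefinedFomError("FOM requires at least one normal and one abnormal case")
    values = np.empty((I1, I2, J))
    for i1, i2, j in itertools.product(range(I1), range(I2), range(J)):
        C = _cell_pair_matrix(ds, i1, i2, j, fom_type)
        values[i1, i2, j] = C.sum() / (K1 * K2)
    return FomMatrix(values=values, fom_type=fom_type)


def jackknife(ds: ScoredDataset, fom_type: str = "wafroc") -> JackknifeSet:
    """Leave-one-case-out FOMs for every cell and every case.

    Because both FOMs are sums over (abnormal, normal) case pairs, deleting a
    case simply drops one row or column of the pair-contribution matrix, so
    the full jackknife costs no more than one FOM evaluation per cell.
    """
    fom_type = _normalize_fom_type(fom_type)
    I1, I2, J = ds.n_factor1, ds.n_factor2, ds.n_readers
    K1, K2 = ds.n_normal, ds.n_abnormal
    if K1 < 2 or K2 < 2:
        raise UndefinedFomError(
            "jackknife requires >= 2 normal and >= 2 abnormal cases "
            "(deleting a case must not empty either set)"
        )
    theta = np.empty((I1, I2, J))
    loo = np.empty((I1, I2, J, K1 + K2))
    for i1, i2, j in itertools.product(range(I1), range(I2), range(J)):
        C = _cell_pair_matrix(ds, i1, i2, j, fom_type)  # (K2, K1)
        total = C.sum()
        theta[i1, i2, j] = total / (K1 * K2)
        # delete normal n: drop column n
        loo[i1, i2, j, :K1] = (total - C.sum(axis=0)) / ((K1 - 1) * K2)
        # delete abnormal a: drop row a
        loo[i1, i2, j, K1:] = (total - C.sum(axis=1)) / (K1 * (K2 - 1))
    return JackknifeSet(
        theta=theta, loo=loo, n_normal=K1, n_abnormal=K2, fom_type=fom_type
    )
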