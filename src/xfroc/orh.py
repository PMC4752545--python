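"""Obuchowski–Rockette / Hillis (ORH) significance testing for MRMC FOM matrices.

Input is an ``I × J`` matrix of figures of merit θ_ij (treatment *i*, reader
*j*).  The random-reader fixed-case (RRFC) analysis treats readers as a random
sample and the case set as fixed — appropriate when the case set is unique
(e.g. a single physical phantom) so conclusions generalize over readers only:

    MS(T)  = J/(I−1) · Σ_i (θ̄_i· − θ̄··)²
    MS(TR) = Σ_ij (θ_ij − θ̄_i· − θ̄_·j + θ̄··)² / ((I−1)(J−1))
    F      = MS(T) / MS(TR)   ~   F(I−1, (I−1)(J−1))  under H0

Pairwise treatment contrasts use t = (θ̄_i· − θ̄_i′·) / sqrt(2·MS(TR)/J) on the
same denominator degrees of freedom, with two-sided p-values and confidence
intervals.  A pair is declared *protected-significant* only when both the
overall F-test and the pairwise t-test fall below the threshold; this guards
the family of pairwise contrasts.

The random-reader random-case (RRRC) analysis adds the Hillis denominator
``MS(TR) + J·max(Cov2 − Cov3, 0)`` with jackknife-estimated covariance
components and the Hillis denominator degrees of freedom.  Covariance
components follow the Obuchowski–Rockette error-covariance structure:
``Cov1`` between treatments within a reader, ``Cov2`` between readers within
a treatment, ``Cov3`` between different readers and treatments, ``Var`` the
mean error variance.  Component estimates may legitimately be negative; they
are reported raw and only the Hillis truncation above is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .dataset import FrocError
from .fom import JackknifeSet


class DegenerateDesignError(FrocError):
    """MS(TR) is numerically zero, so the F statistic is undefined."""


@dataclass(frozen=True)
class PairwiseComparison:
    """One treatment contrast: difference, CI, t statistic and protection flag."""

    i: int
    i_prime: int
    difference: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    protected_significant: bool = False


@dataclass(frozen=True)
class CovComponents:
    """Jackknife covariance components of the OR error structure (raw, untruncated)."""

    cov1: float
    cov2: float
    cov3: float
    var: float
    matrix: np.ndarray | None = field(default=None, compare=False, repr=False)


@dataclass
class OrhResult:
    """Outcome of a single-factor ORH analysis of an I × J FOM matrix."""

    design: str                      # "RRFC" or "RRRC"
    level_means: np.ndarray          # θ̄_i·, length I
    f: float
    ndf: int
    ddf: float
    p: float
    ms_treatment: float
    ms_treatment_reader: float
    pairwise: list[PairwiseComparison]
    alpha: float
    cov: CovComponents | None = None


def _mean_squares(theta: np.ndarray) -> tuple[float, float]:
    I, J = theta.shape
    row = theta.mean(axis=1)
    col = theta.mean(axis=0)
    grand = theta.mean()
    ms_t = J / (I - 1) * float(((row - grand) ** 2).sum())
    resid = theta - row[:, None] - col[None, :] + grand
    ms_tr = float((resid ** 2).sum()) / ((I - 1) * (J - 1))
    return ms_t, ms_tr


def _pairwise_table(
    row_means: np.ndarray, denom: float, J: int, ddf: float, alpha: float
) -> list[PairwiseComparison]:
    se = np.sqrt(2.0 * denom / J)
    tcrit = stats.t.ppf(1 - alpha / 2, ddf)
    table = []
    I = len(row_means)
    for i in range(I):
        for ip in range(i + 1, I):
            diff = float(row_means[i] - row_means[ip])
            t = diff / se
            p = 2 * float(stats.t.sf(abs(t), ddf))
            table.append(
                PairwiseComparison(
                    i=i, i_prime=ip, difference=diff,
                    ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
                    t=t, p=p,
                )
            )
    return table


def rrfc_analysis(theta: np.ndarray, alpha: float = 0.05) -> OrhResult:
    """Random-reader fixed-case ORH analysis of an I × J FOM matrix.

    Raises :class:`DegenerateDesignError` when the treatment-by-reader mean
    square is numerically zero (toy data); a silent infinite F would corrupt
    downstream multiple-comparison logic.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] < 2 or theta.shape[1] < 2:
        raise ValueError("rrfc_analysis needs an I x J matrix with I >= 2, J >= 2")
    if not np.isfinite(theta).all():
        raise ValueError("FOM matrix contains non-finite values")
    I, J = theta.shape
    ms_t, ms_tr = _mean_squares(theta)
    if ms_tr <= 1e-14:
        raise DegenerateDesignError(
            f"MS(TR) = {ms_tr:.3g} is numerically zero; F is undefined"
        )
    ndf, ddf = I - 1, (I - 1) * (J - 1)
    f = ms_t / ms_tr
    p = float(stats.f.sf(f, ndf, ddf))
    result = OrhResult(
        design="RRFC",
        level_means=theta.mean(axis=1),
        f=f, ndf=ndf, ddf=float(ddf), p=p,
        ms_treatment=ms_t, ms_treatment_reader=ms_tr,
        pairwise=_pairwise_table(theta.mean(axis=1), ms_tr, J, ddf, alpha),
        alpha=alpha,
    )
    return protected_pairwise(result)


def jackknife_covariances(jk: JackknifeSet) -> CovComponents:
    """Estimate OR covariance components from leave-one-case-out FOMs.

    ``jk.loo`` must be shaped ``(I, J, K)`` over a common case set.  The
    covariance between cells (i, j) and (i′, j′) is the jackknife estimate
    ``(K−1)/K · Σ_k (θ_{ij(k)} − θ̄_{ij(·)})(θ_{i′j′(k)} − θ̄_{i′j′(·)})``.
    """
    loo = np.asarray(jk.loo, dtype=float)
    if loo.ndim != 3:
        raise ValueError(
            "jackknife_covariances expects a two-level (treatment x reader) "
            "JackknifeSet with loo shaped (I, J, K); collapse crossed factors first"
        )
    I, J, K = loo.shape
    if K != jk.n_cases:
        raise FrocError("leave-one-out axis does not match the case count")
    d = loo - loo.mean(axis=2, keepdims=True)
    flat = d.reshape(I * J, K)
    cov = (K - 1) / K * (flat @ flat.T)

    t_of = np.arange(I * J) // J
    r_of = np.arange(I * J) % J
    same_t = t_of[:, None] == t_of[None, :]
    same_r = r_of[:, None] == r_of[None, :]
    diag = np.eye(I * J, dtype=bool)
    masks = {
        "var": diag,
        "cov1": same_r & ~same_t,            # same reader, different treatment
        "cov2": same_t & ~same_r,            # same treatment, different reader
        "cov3": ~same_t & ~same_r,
    }

    def mean_over(mask: np.ndarray) -> float:
        return float(cov[mask].mean()) if mask.any() else 0.0

    return CovComponents(
        cov1=mean_over(masks["cov1"]),
        cov2=mean_over(masks["cov2"]),
        cov3=mean_over(masks["cov3"]),
        var=mean_over(masks["var"]),
        matrix=cov,
    )


def rrrc_analysis(
    theta: np.ndarray, cov: CovComponents, alpha: float = 0.05
) -> OrhResult:
    """Random-reader random-case ORH analysis with the Hillis denominator.

    F = MS(T) / [MS(TR) + J·max(Cov2 − Cov3, 0)], referred to
    F(I−1, ddf_H) with the Hillis denominator degrees of freedom
    ddf_H = denom² / (MS(TR)² / ((I−1)(J−1))).  When Cov2 ≤ Cov3 this reduces
    exactly to the fixed-case analysis.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] < 2 or theta.shape[1] < 2:
        raise ValueError("rrrc_analysis needs an I x J matrix with I >= 2, J >= 2")
    I, J = theta.shape
    ms_t, ms_tr = _mean_squares(theta)
    if ms_tr <= 1e-14:
        raise DegenerateDesignError(
            f"MS(TR) = {ms_tr:.3g} is numerically zero; F is undefined"
        )
    denom = ms_tr + J * max(cov.cov2 - cov.cov3, 0.0)
    ndf = I - 1
    ddf = denom ** 2 / (ms_tr ** 2 / ((I - 1) * (J - 1)))
    f = ms_t / denom
    p = float(stats.f.sf(f, ndf, ddf))
    result = OrhResult(
        design="RRRC",
        level_means=theta.mean(axis=1),
        f=f, ndf=ndf, ddf=float(ddf), p=p,
        ms_treatment=ms_t, ms_treatment_reader=ms_tr,
        pairwise=_pairwise_table(theta.mean(axis=1), denom, J, ddf, alpha),
        alpha=alpha,
        cov=cov,
    )
    return protected_pairwise(result)


def protected_pairwise(result: OrhResult, alpha: float | None = None) -> OrhResult:
    """Flag each pair significant iff both the overall F p and the pairwise p < alpha.

    Returns a copy of ``result`` with the flags (and ``alpha``, if given) set.
    """
    alpha = result.alpha if alpha is None else alpha
    overall = result.p < alpha
    pairwise = [
        replace(pc, protected_significant=bool(overall and pc.p < alpha))
        for pc in result.pairwise
    ]
    out = OrhResult(**{**result.__dict__, "pairwise": pairwise, "alpha": alpha})
    return out
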