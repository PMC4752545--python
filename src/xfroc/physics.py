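"""Ancillary image-quality and dosimetry metrics: CNR, its factor trend, effective dose.

Contrast-to-noise ratio uses the standard single-background-ROI definition

    CNR = |mean(nodule ROI) − mean(background ROI)| / SD(background ROI),

in Hounsfield units; contrast (the numerator) is reported separately because
reconstruction methods should not change HU means, only the noise.

Effective dose follows ICRP Publication 103: E = Σ_T w_T · H_T (mSv), where
H_T is the equivalent dose to tissue T (numerically equal to absorbed dose in
mGy for photons, radiation weighting factor 1) and the tissue weighting
factors w_T sum to one.  The thirteen remainder tissues share a single
w = 0.12 applied to their arithmetic-mean dose.  The shipped weighting table
can be replaced by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import FrocError

# ---------------------------------------------------------------------------
# ICRP 103 tissue weighting (versioned configuration data)
# ---------------------------------------------------------------------------

#: Named-tissue weighting factors, ICRP Publication 103 (2007).
ICRP103_TISSUE_WEIGHTS: dict[str, float] = {
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}

#: The 13 remainder tissues pool a single weight of 0.12 on their mean dose.
ICRP103_REMAINDER_WEIGHT: float = 0.12
ICRP103_REMAINDER_ORGANS: tuple[str, ...] = (
    "adrenals", "extrathoracic_region", "gall_bladder", "heart", "kidneys",
    "lymphatic_nodes", "muscle", "oral_mucosa", "pancreas", "prostate_uterus",
    "small_intestine", "spleen", "thymus",
)


class UnknownOrganError(FrocError):
    """An organ dose was supplied for a tissue absent from the weighting table."""


@dataclass
class OrganDoseSet:
    """Absorbed organ doses (mGy) with an ICRP-style tissue-weighting table.

    Organs not present in ``doses`` are taken as 0 mGy (dosimetry phantoms
    instrument a subset of tissues).  Doses must be non-negative and every
    dosed organ must appear in the weighting table (named or remainder).
    """

    doses: dict[str, float]
    weights: dict[str, float] = field(
        default_factory=lambda: dict(ICRP103_TISSUE_WEIGHTS)
    )
    remainder_weight: float = ICRP103_REMAINDER_WEIGHT
    remainder_organs: tuple[str, ...] = ICRP103_REMAINDER_ORGANS


def effective_dose(d: OrganDoseSet | Mapping[str, float]) -> float:
    """ICRP-103 effective dose in mSv from absorbed organ doses in mGy.

    Raises :class:`UnknownOrganError` for unrecognized organ names and
    :class:`FrocError` if the weighting table does not sum to 1 (tolerance
    1e-9) or any dose is negative.
    """
    if not isinstance(d, OrganDoseSet):
        d = OrganDoseSet(doses=dict(d))
    total_w = sum(d.weights.values()) + d.remainder_weight
    if abs(total_w - 1.0) > 1e-9:
        raise FrocError(f"tissue weights sum to {total_w!r}, expected 1")
    known = set(d.weights) | set(d.remainder_organs)
    unknown = sorted(set(d.doses) - known)
    if unknown:
        raise UnknownOrganError(f"unknown organ name(s): {unknown}")
    if any(v < 0 for v in d.doses.values()):
        raise FrocError("organ doses must be >= 0")
    e = sum(w * d.doses.get(organ, 0.0) for organ, w in d.weights.items())
    if d.remainder_organs:
        remainder_mean = sum(
            d.doses.get(organ, 0.0) for organ in d.remainder_organs
        ) / len(d.remainder_organs)
        e += d.remainder_weight * remainder_mean
    return float(e)


# ---------------------------------------------------------------------------
# Contrast-to-noise ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiMeasurement:
    """Paired nodule/background ROI statistics for one nodule on one image."""

    nodule_mean: float       # HU
    background_mean: float   # HU
    background_sd: float     # HU
    mas: float               # tube current-time product
    reconstruction: str      # e.g. "FBP" or "IR"/"AIDR3D"

    def __post_init__(self) -> None:
        if not self.background_sd > 0:
            raise FrocError("background_sd must be > 0")


def contrast(m: RoiMeasurement) -> float:
    """Absolute nodule-background contrast in HU."""
    return abs(m.nodule_mean - m.background_mean)


def cnr(m: RoiMeasurement) -> float:
    """Contrast-to-noise ratio |μ_nodule − μ_background| / σ_background."""
    return contrast(m) / m.background_sd


def _is_iterative(reconstruction: str) -> int:
    return 0 if reconstruction.strip().upper() == "FBP" else 1


@dataclass
class CnrTrendResult:
    """OLS fit of CNR on mAs (continuous) and reconstruction (indicator).

    The indicator is 1 for iterative reconstruction and 0 for FBP, so
    ``params["iterative"]`` is the CNR advantage of IR at fixed mAs.
    """

    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    nobs: int
    rsquared: float
    alpha: float = 0.05

    def significant(self, term: str) -> bool:
        return self.pvalues[term] < self.alpha


def cnr_trend(
    measurements: Sequence[RoiMeasurement], alpha: float = 0.05
) -> CnrTrendResult:
    """Two-factor linear least-squares trend of CNR over mAs and reconstruction.

    Requires at least three measurements spanning both factors; a
    rank-deficient design (single mAs level or single reconstruction method)
    raises :class:`FrocError`.
    """
    if len(measurements) < 3:
        raise FrocError("cnr_trend needs at least 3 measurements")
    y = np.array([cnr(m) for m in measurements])
    X = pd.DataFrame(
        {
            "const": 1.0,
            "mas": [m.mas for m in measurements],
            "iterative": [float(_is_iterative(m.reconstruction)) for m in measurements],
        }
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FrocError(
            "rank-deficient design: need >= 2 mAs levels and both reconstruction methods"
        )
    fit = sm.OLS(y, X).fit()
    return CnrTrendResult(
        params=dict(fit.params),
        bse=dict(fit.bse),
        tvalues=dict(fit.tvalues),
        pvalues=dict(fit.pvalues),
        nobs=int(fit.nobs),
        rsquared=float(fit.rsquared),
        alpha=alpha,
    )
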