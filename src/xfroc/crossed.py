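"""Crossed-modality analysis: two sequential single-factor ORH analyses.

When the imaging condition is defined by two fully crossed factors (e.g. four
mAs levels x two reconstruction methods) the figure of merit carries three
indices, θ_{i1 i2 j}.  Comparing all I1·I2 conditions pairwise would cost
I(I−1)/2 = 28 comparisons at I = 8 and would not answer the questions of
interest.  Instead, two sequential analyses are run:

* **factor-1 analysis** (mAs analysis): θ is averaged over the factor-2
  index, θ_{i1·j} = (1/I2) Σ_{i2} θ_{i1 i2 j}, and a standard single-factor
  ORH analysis is applied to the resulting I1 × J matrix;
* **factor-2 analysis** (reconstruction analysis): symmetrically with
  θ_{·i2 j}.

FOMs — not ratings — are averaged, exactly as the dot notation specifies.
Because two hypothesis families are tested on the same data, a Bonferroni
correction divides the overall α equally between them (0.05 → 0.025 per
analysis by default), conservatively maintaining the family-wise type-I error
at the overall level.  Within each analysis a pair is declared significant
only if both the overall F-test and the pairwise t-test are below the
per-analysis threshold.

The jackknife pseudovalues are linear in θ, so averaging pseudovalues over a
factor is identical to jackknifing the factor-averaged FOM;
:func:`collapse_jackknife` exploits this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import ScoredDataset
from .fom import FomMatrix, JackknifeSet, fom_matrix, jackknife
from .orh import OrhResult, rrfc_analysis

_FACTOR_AXES = {"factor1": 1, "factor2": 0}  # axis averaged *over*


def n_pairwise(I: int) -> int:
    """Number of distinct level pairs, I(I−1)/2."""
    if I < 1:
        raise ValueError("level count must be >= 1")
    return I * (I - 1) // 2


def average_over_factor(fom: FomMatrix, which: str) -> np.ndarray:
    """Collapse the 3-way FOM array for the analysis of one factor.

    ``which`` names the factor being *analyzed*: ``"factor1"`` returns
    θ_{i1·j} (shape ``(I1, J)``, averaged over factor 2) and ``"factor2"``
    returns θ_{·i2 j} (shape ``(I2, J)``).
    """
    if which not in _FACTOR_AXES:
        raise ValueError("which must be 'factor1' or 'factor2'")
    return fom.values.mean(axis=_FACTOR_AXES[which])


def collapse_jackknife(jk: JackknifeSet, which: str) -> JackknifeSet:
    """Average a crossed-design jackknife over one factor (exact, by linearity).

    ``jk.theta`` must be shaped ``(I1, I2, J)``.  The result is a two-level
    set suitable for :func:`xfroc.orh.jackknife_covariances`.
    """
    if jk.theta.ndim != 3:
        raise ValueError("collapse_jackknife expects a crossed (I1, I2, J) JackknifeSet")
    if which not in _FACTOR_AXES:
        raise ValueError("which must be 'factor1' or 'factor2'")
    axis = _FACTOR_AXES[which]
    return JackknifeSet(
        theta=jk.theta.mean(axis=axis),
        loo=jk.loo.mean(axis=axis),
        n_normal=jk.n_normal,
        n_abnormal=jk.n_abnormal,
        fom_type=jk.fom_type,
    )


@dataclass
class CrossedResult:
    """Both sequential ORH analyses of a crossed two-factor FROC study."""

    factor1_analysis: OrhResult   # e.g. mAs; FOM averaged over factor 2
    factor2_analysis: OrhResult   # e.g. reconstruction; FOM averaged over factor 1
    bonferroni_alpha: float
    n_analyses: int
    fom_type: str

    @property
    def any_significant(self) -> bool:
        """True if either analysis flags any protected-significant pair."""
        return any(
            pc.protected_significant
            for res in (self.factor1_analysis, self.factor2_analysis)
            for pc in res.pairwise
        )

    def summary(self, factor1_name: str = "factor 1", factor2_name: str = "factor 2") -> str:
        lines = []
        for name, res in (
            (factor1_name, self.factor1_analysis),
            (factor2_name, self.factor2_analysis),
        ):
            lines.append(
                f"{name} analysis: F({res.ndf}, {res.ddf:g}) = {res.f:.2f}, "
                f"p = {res.p:.3f}" + (" *" if res.p < res.alpha else "")
            )
            for pc in res.pairwise:
                flag = "significant" if pc.protected_significant else "ns"
                lines.append(
                    f"  levels {pc.i} vs {pc.i_prime}: diff = {pc.difference:+.4f} "
                    f"[{pc.ci_low:+.4f}, {pc.ci_high:+.4f}], p = {pc.p:.3f} ({flag})"
                )
        lines.append(
            f"threshold per analysis (Bonferroni over {self.n_analyses}): "
            f"{self.bonferroni_alpha:g}"
        )
        return "\n".join(lines)


def crossed_modality_analysis(
    ds: ScoredDataset,
    fom_type: str = "wafroc",
    overall_alpha: float = 0.05,
    n_analyses: int = 2,
) -> CrossedResult:
    """Run the full crossed-modality RRFC procedure on a scored dataset.

    Computes the per-cell FOM matrix, collapses it once over each factor,
    runs the random-reader fixed-case ORH analysis on each collapsed matrix
    at the Bonferroni-corrected level ``overall_alpha / n_analyses``, and
    applies the both-tests protection rule to each pairwise table.
    """
    if ds.n_factor1 < 2 or ds.n_factor2 < 2:
        raise ValueError("crossed analysis requires >= 2 levels of each factor")
    if not 0 < overall_alpha <= 1:
        raise ValueError("overall_alpha must lie in (0, 1]")
    alpha = overall_alpha / n_analyses
    fm = fom_matrix(ds, fom_type)
    res1 = rrfc_analysis(average_over_factor(fm, "factor1"), alpha=alpha)
    res2 = rrfc_analysis(average_over_factor(fm, "factor2"), alpha=alpha)
    return CrossedResult(
        factor1_analysis=res1,
        factor2_analysis=res2,
        bonferroni_alpha=alpha,
        n_analyses=n_analyses,
        fom_type=fm.fom_type,
    )


@dataclass(frozen=True)
class GroupTtestResult:
    """Welch comparison of reader-averaged FOMs between two reader groups."""

    t: float
    df: float
    p: float
    mean_difference: float
    ci_low: float
    ci_high: float
    group_labels: tuple[str, str]


def reader_group_ttest(
    fom: FomMatrix, group_labels, confidence: float = 0.95
) -> GroupTtestResult:
    """Welch's unequal-variance t-test between two groups of readers.

    Each reader's summary performance is the unweighted mean of their FOM
    over all design cells (appropriate for a balanced design).  Groups are
    defined by ``group_labels`` (one label per reader, exactly two distinct
    values, each group with at least two readers).  Returns the two-sided
    Satterthwaite-df test and the confidence interval of the group mean
    difference (first label minus second, in sorted label order).
    """
    labels = list(group_labels)
    if len(labels) != fom.n_readers:
        raise ValueError("need one group label per reader")
    uniq = sorted(set(map(str, labels)))
    if len(uniq) != 2:
        raise ValueError("reader_group_ttest requires exactly two groups")
    per_reader = fom.values.mean(axis=(0, 1))
    a = per_reader[[str(l) == uniq[0] for l in labels]]
    b = per_reader[[str(l) == uniq[1] for l in labels]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each reader group needs at least two readers")
    if a.var(ddof=1) < 1e-24 and b.var(ddof=1) < 1e-24:
        # degenerate zero-variance groups: no evidence against equality when
        # the means coincide, overwhelming evidence when they do not
        diff = float(a.mean() - b.mean())
        equal = abs(diff) < 1e-12
        t = 0.0 if equal else float(np.inf) * np.sign(diff)
        return GroupTtestResult(
            t=t, df=float(len(a) + len(b) - 2),
            p=1.0 if equal else 0.0,
            mean_difference=diff, ci_low=diff, ci_high=diff,
            group_labels=(uniq[0], uniq[1]),
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence)
    return GroupTtestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        group_labels=(uniq[0], uniq[1]),
    )
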