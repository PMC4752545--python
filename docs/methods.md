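# Methods

## The free-response paradigm and the data model

In a free-response (FROC) study a reader marks every suspicious location on a
case and rates each mark's confidence.  Marks within an acceptance radius of
a true lesion are lesion localizations (LL); all others are non-lesion
localizations (NL).  A case may carry zero, one, or many marks, so the data
are ragged; `xfroc` stores them densely on a
`(factor1, factor2, reader, case, slot)` grid with the sentinel `-inf` for
unmarked lesions and empty slots.  The sentinel is strictly below every legal
rating, so the comparison kernel ψ (1 / ½ / 0 for win / tie / loss) applies
uniformly to marked and unmarked entities: an unmarked lesion loses every
strict comparison, and two unmarked entities tie at ½.

**Tie convention.** A reader who marks nothing at all therefore scores
θ = 0.5 (all ψ(−∞, −∞) pairs), not 0.  The alternative convention — flooring
unmarked-lesion contributions at 0 — would make the wAFROC of a silent
observer depend on the number of unmarked normals; the ½ tie keeps the FOM an
empirical probability with the usual chance anchor.  This choice is baked
into ψ and documented here because FROC literature does not fix it uniformly.

**Mark classification.** Distance exactly equal to the acceptance radius
(default 20 px, Euclidean in pixel units) counts as within; ties between
equidistant lesions break toward the lowest lesion id (determinism).  When
several marks hit one lesion the highest rating becomes the LL; the surplus
marks are *discarded* by default, because a pop-up-rating interface yields
one deliberate mark per perceived nodule and demoting surplus marks to NL
would double-count perception events.  `surplus_policy="demote_to_nl"` is
available for sensitivity analysis.

**Completeness.** The ORH formulas assume a balanced, fully crossed design,
so a missing (factor1, factor2, reader) cell is an error, never imputed.  In
the CSV reader a cell with zero rows is indistinguishable from a missing
cell and is likewise rejected; real observer data at study scale always
contain at least one mark per condition.

## Figures of merit

The equally weighted JAFROC FOM for one cell is

θ = (1 / K₁K₂) Σₙ Σₐ Σ_ℓ W_{aℓ} ψ(LL_{aℓ}, FPₙ),

where FPₙ is the highest NL rating on normal case *n* and W_{aℓ} = 1/n_a
(equal per-case weights summing to 1).  False positives come **only from
normal cases**; NLs on abnormal cases affect only the inferred-ROC rating.
The inferred-ROC AUC applies the same kernel to per-case highest ratings
(over all NL and LL marks).  Both FOMs depend only on rating order, so they
are invariant under strictly increasing transforms — a property the test
suite checks, and the reason the simulator's latent Gaussian ratings and
their 1–10 discretization give similar analyses.

Both FOMs are sums over (abnormal, normal) case pairs, so the
leave-one-case-out jackknife is computed from the pair-contribution matrix
at the cost of a single FOM evaluation per cell.  Pseudovalues
Y_k = K·θ − (K−1)·θ_(k) are linear in θ; consequently averaging pseudovalues
over a factor is *exactly* the jackknife of the factor-averaged FOM, which
the crossed analysis exploits and a test asserts to 1e-12.

## Significance testing

**RRFC.** With the case set fixed (a unique physical phantom generalizes to
no case population) and readers random, the two-way ANOVA of θ_ij gives
F = MS(T)/MS(TR) on (I−1, (I−1)(J−1)) df.  Pairwise contrasts use
t = Δ/√(2·MS(TR)/J) with the same df; the CI and the p-value are dual (the
CI excludes 0 iff p < α).  MS(TR) ≤ 1e-14 raises an error rather than
reporting p = 0: it occurs only in toy or duplicated data, and a silent
infinite F would corrupt the multiple-comparison logic downstream.

**RRRC.** The Hillis denominator MS(TR) + J·max(Cov2 − Cov3, 0) with
jackknife covariance components and Hillis df
denom²/(MS(TR)²/((I−1)(J−1))).  Component estimates may be negative and are
reported raw; only the denominator truncation is applied.  When
Cov2 = Cov3 the analysis reduces exactly to RRFC (tested).

**Crossed-modality procedure.** FOMs (never ratings) are averaged over the
factor not under analysis, and each collapsed I × J matrix gets a standard
RRFC analysis at α = overall/2 (0.025 for the default 0.05 over two
analyses).  A pair is significant only when both the overall F and the
pairwise t clear the threshold.  The family-wise type-I error of the whole
procedure is estimated by Monte-Carlo in `null_rejection_rate`; at the
validation design (2×2 cells, 4 readers, 20+20 cases, 1000 replicates) it
sits at the nominal 0.05 within Monte-Carlo error.  With small reader
panels the F reference distribution is only approximate (reader-averaged
FOMs are not exactly normal), which is why the calibration is verified by
simulation rather than assumed.

**Reader groups.** Professional groups (e.g. radiologists vs. radiographers)
are compared with Welch's unequal-variance t-test on per-reader FOMs, each
reader summarized by the unweighted mean over all design cells (appropriate
for a balanced design).  Zero-variance degenerate groups short-circuit to
t = 0, p = 1 (equal means) instead of propagating NaNs.

## The simulator

Per (cell, reader, case): NL count ~ Poisson(λ), NL ratings ~ N(b_j, 1);
each lesion is marked with probability ν and rated N(μ_{i₁i₂} + b_j, 1),
with reader offsets b_j ~ N(0, σ_r²).  Defaults mirror the motivating
study's conditions: 4 × 2 × 11 design, 34 normal + 34 abnormal cases,
per-case lesion counts drawn with probabilities (23, 10, 1)/34 over {1, 2, 3}
(the phantom allocation), λ = 1.0, ν = 0.9, μ = 2.0 and σ_r = 0.2 — chosen
once to put cell wAFROC values in the high-0.8 range reported for human
observers at this task — and ratings discretized to the 1–10 integer scale
with fixed equal-width cut points (width 0.75 anchored at −2.5 on the latent
scale; data-independent, hence deterministic).

Random streams split per (cell, reader, case) via `SeedSequence` spawn keys,
so enlarging one design dimension leaves all other draws untouched (tested).

What the generator does *not* emulate: visual search (NL counts are
independent of detectability), intra-case correlation between lesions,
case-difficulty variation beyond lesion count, rating degradation at low
dose asymmetric between factors, or reader training effects.  Passing
validation tests therefore demonstrates the *statistical machinery* is
calibrated under a plausible data-generating process, not that any
particular clinical effect size is realistic.

## Phantom truth fixture

`make_phantom_truth` reproduces the published nodule distribution of the
anthropomorphic chest phantom: 46 nodules over 34 abnormal cases
(23 × 1, 10 × 2, 1 × 3 — the unique {1,2,3} allocation whose mean is 1.35
and sample SD rounds to 0.54), zone-by-zone cell counts with margins
25:21 right:left, 8:26:12 upper:mid:lower, 8:25:13
anterior:posterior:central, and 18 peripheral nodules; diameters in
{5, 8, 10, 12} mm and densities in {+100, −630, −800} HU.  The published
per-zone peripheral breakdown is internally inconsistent with the main grid
in one cell (the lower-left group holds 4 nodules but lists 5 peripheral),
so one peripheral flag is carried by the lower-right group instead; all
totals and all main-grid cell counts are exact on every run.  Coordinates
are placed inside side/depth pixel boxes on the 512 × 512 grid with a 50 px
minimum separation between same-case nodules, so the 20 px acceptance
radius is unambiguous.

## Physics metrics

CNR = |μ_nodule − μ_background| / σ_background from paired ROI statistics —
the standard single-background-ROI definition; contrast is reported
separately since reconstruction should change only the noise.  The
two-factor trend is an ordinary least-squares fit of CNR on mAs (continuous)
and an iterative-reconstruction indicator, with coefficient t-tests;
rank-deficient designs are rejected.  Effective dose is the ICRP-103
tissue-weighted sum of organ equivalent doses (photon radiation weighting
1), with the 13 remainder tissues pooling w = 0.12 on their mean dose; the
weighting table ships as a versioned in-package table and can be replaced
per call.  Organs without
a supplied dose count as 0 mGy, since dosimetry phantoms instrument a
subset of tissues.

## Problem sizes used in validation

The acceptance-level checks run at: full study design (4 × 2 × 11, 68
cases) for degrees-of-freedom structure; 1000 random tiny datasets
(K₁, K₂ ≤ 5, ≤ 3 lesions) against brute-force pair-enumeration oracles;
1000 null replicates at a 2 × 2 × 4-reader, 40-case design for the
family-wise type-I error; 1000 random 2 × J matrices for the F = t²
identity.  These sizes give Monte-Carlo standard errors below 0.01 on
rejection rates while keeping the whole suite at well under a minute.

## Known limitations

- No fixed-reader random-case (FRRC) analysis, sample-size estimation, or
  equivalence testing; failing to reject equality is never evidence of
  equivalence.
- No FROC curve fitting (only empirical FOMs); no import shims for other
  FROC packages' spreadsheet dialects.
- The RRRC path is provided for completeness but the crossed procedure runs
  fixed-case analyses, matching the single-phantom design it was built for.
- Effective risk modelling (age/sex-dependent cancer-risk coefficients) is
  out of scope; only effective dose is computed.
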