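# xfroc — crossed-modality JAFROC analysis for free-response observer studies

`xfroc` analyzes free-response (FROC) observer studies in which the imaging
condition is defined by **two fully crossed factors** — for example CT tube
current–time product (mAs, 4 levels) crossed with image reconstruction method
(FBP vs. iterative, 2 levels), read by *J* readers over a fixed case set.
It is aimed at medical-imaging researchers running multi-reader multi-case
(MRMC) detection experiments who need location-aware figures of merit and
valid significance tests for factorial designs.

## What it computes

**Figures of merit.** For each design cell (*i₁*, *i₂*, *j*) the equally
weighted JAFROC figure of merit

θ = (1 / K₁K₂) Σₙ Σₐ Σ_ℓ W_{aℓ} ψ(LLₐℓ, FPₙ),  ψ(a,b) = 1 if a>b, ½ if a=b, 0 if a<b,

the weighted empirical probability that a lesion rating exceeds the highest
rating FPₙ on a normal case, with per-case lesion weights W summing to 1
(every case counts equally).  For consistency checking, the **inferred-ROC**
AUC uses each case's highest rating as its single ROC rating.

**Crossed-modality significance testing.**  Instead of all I(I−1)/2 = 28
pairwise comparisons among the 8 conditions, two sequential single-factor
analyses are run on factor-averaged FOMs (θ_{i₁·j} and θ_{·i₂j}), each with
the random-reader fixed-case Obuchowski–Rockette/Hillis (ORH) method:
F = MS(T)/MS(TR) on (I−1, (I−1)(J−1)) degrees of freedom, with pairwise
t-tests and confidence intervals on the same denominator.  A Bonferroni
correction splits the overall α = 0.05 into 0.025 per analysis, and a pair is
declared significant only when **both** the overall F and the pairwise t are
significant.  Random-reader random-case (RRRC) analysis with
jackknife-estimated covariance components and the Hillis denominator is also
provided.

**Validation machinery.**  A search-model rating simulator (Poisson
non-lesion marks, Bernoulli lesion hits, Gaussian ratings with per-cell
detectability and reader effects) supports type-I-error and power studies; a
phantom truth fixture reproduces the 34 normal / 34 abnormal case set with 46
nodules used in the motivating study.  Ancillary physics metrics cover
nodule contrast-to-noise ratio (CNR), its two-factor least-squares trend, and
ICRP-103 effective dose.

## Worked example

```python
from xfroc import SimConfig, simulate_froc, crossed_modality_analysis

ds = simulate_froc(SimConfig(seed=1))      # 4 x 2 x 11 design, 34 + 34 cases
result = crossed_modality_analysis(ds, "wafroc", overall_alpha=0.05)
print(result.summary("mAs", "reconstruction"))
```

prints

```
mAs analysis: F(3, 30) = 1.37, p = 0.271
  levels 0 vs 1: diff = +0.0232 [-0.0074, +0.0539], p = 0.083 (ns)
  levels 0 vs 2: diff = +0.0223 [-0.0084, +0.0529], p = 0.097 (ns)
  levels 0 vs 3: diff = +0.0160 [-0.0146, +0.0466], p = 0.227 (ns)
  levels 1 vs 2: diff = -0.0010 [-0.0316, +0.0296], p = 0.940 (ns)
  levels 1 vs 3: diff = -0.0072 [-0.0379, +0.0234], p = 0.581 (ns)
  levels 2 vs 3: diff = -0.0062 [-0.0369, +0.0244], p = 0.634 (ns)
reconstruction analysis: F(1, 10) = 0.17, p = 0.687
  levels 0 vs 1: diff = +0.0030 [-0.0160, +0.0220], p = 0.687 (ns)
threshold per analysis (Bonferroni over 2): 0.025
```

The simulator default puts the same detectability in every cell, so neither
factor shows an effect: the mAs analysis F(3, 30) and the reconstruction
analysis F(1, 10) are both far from the 0.025 threshold, every pairwise 95%
CI straddles zero, and no pair is flagged.  With a per-cell `detectability`
matrix that rises with the first factor, the mAs analysis F becomes large
while the reconstruction analysis stays null (see the tests for examples).

The same pipeline runs from the shell:

```bash
xfroc simulate --config sim.json --seed 1 --out scored.csv
xfroc score --marks marks.csv --truth truth.csv --radius 20 --out scored.csv
xfroc analyze --scored scored.csv --truth truth.csv --fom wafroc --out report.json
xfroc typeI --reps 1000 --alpha 0.05
xfroc cnr --measurements rois.csv --out cnr.json
xfroc dose --doses organ_doses.csv
```

## Layout

- `xfroc.dataset` — truth tables, the dense rating container, CSV I/O, validation
- `xfroc.scoring` — acceptance-radius LL/NL mark classification
- `xfroc.fom` — wAFROC and inferred-ROC FOMs, jackknife pseudovalues
- `xfroc.orh` — RRFC/RRRC ORH analysis, jackknife covariance components
- `xfroc.crossed` — factor averaging, the two-analysis Bonferroni procedure, reader-group Welch test
- `xfroc.simulate` — rating simulator, phantom truth fixture, type-I-error estimation
- `xfroc.physics` — CNR, CNR trend, ICRP-103 effective dose
- `xfroc.cli` — the `xfroc` command

See `docs/methods.md` for the statistical model, conventions and limitations.
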