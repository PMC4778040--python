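# spermcomp

Statistical machinery for validating a fluorescent sperm-labelling
technique in sperm-competition experiments with a broadcast-spawning
mussel. When a vital mitochondrial dye is used to mark one male's sperm,
the marking itself must not change sperm performance. `spermcomp`
implements the two paired dyed-vs-undyed comparisons that establish this,
and the simulation-based power analysis that quantifies how small a dye
effect the competitive design could have detected:

1. **Motility** — per-male paired CASA summaries (percent motile plus the
   seven kinematic traits VAP, VSL, VCL, STR, LIN, ALH, BCF). A paired
   *t*-test on percent motile; per-male undyed − dyed trait differences
   with a Shapiro–Wilk normality screen and a square-root transform of
   flagged traits; correlation-matrix PCA of the differences with Kaiser
   retention (λ > 1); one-sample *t*-tests on the retained PC scores.
2. **Competitive fertilisation** — a reciprocal three-cross design per
   pair of competing males: cross A dyes the focal male (success *X*),
   cross B dyes the rival (success *Y*), cross C dyes nobody (overall
   fertilisation rate *Z*). Under no dye effect *X* = *Z* − *Y*, so the
   focal male's dyed share *X* is compared with his implied undyed share
   (*Z* − *Y*)/*Z* using a binomial logit GLMM

   k_ij ~ Binomial(m_ij, p_ij), logit(p_ij) = β₀ + β₁·dye_ij + u_i,
   u_i ~ N(0, σ_u²),

   fitted by maximising the Laplace-approximated marginal likelihood,
   with Wald *t* inference (residual df = n − 3), deviance/Pearson
   dispersion diagnostics, and an observation-level random-effect (OLRE)
   variant that absorbs overdispersion.
3. **Power** — for each effect size δ on a grid, 1000 paired binomial
   experiments (10 pairs, 100 eggs per observation, undyed share 0.5,
   dyed share 0.5 − δ) are drawn, refitted with the GLMM, and power is
   the fraction of significant Wald *t* tests; the 0.8-power crossing of
   the isotonically smoothed curve gives the minimum detectable effect.

The original study deposited no raw data, so a seeded synthetic-data
module generates motility and fertilisation datasets with the statistical
structure the analyses assume (18 motility pairs, 10 competition pairs,
calibrated to the study's printed summary statistics). Every stage is
therefore testable end to end without any download.

## Worked example

```python
import spermcomp as sc
from spermcomp.config import FertilisationGenConfig, MotilityGenConfig

# paired motility comparison on a synthetic 18-male dataset
samples = sc.generate_motility(MotilityGenConfig(), seed=7)
motility = sc.run_motility_analysis(samples)

# reciprocal-cross fertilisation trials, overdispersed regime, no dye effect
trials = sc.generate_fertilisation(FertilisationGenConfig.realistic_preset(), seed=8)
result = sc.dye_effect_analysis(sc.assemble_pairs(trials))
```

prints, via the bundled reporting helpers:

```
percent motile: t_17 = 0.87, P = 0.40
eigenvalues: [3.78 1.8  0.84 0.31 0.14 0.1  0.03]
mean fertilisation rate 0.673 ± 0.039, range 0.48-0.89
mean dyed-undyed difference -0.007 ± 0.057
Wald t_17 = 0.24, P = 0.813
residual deviance 51.33 on 17 df, dispersion = 3.02
OLRE: dispersion 0.27, Wald Z = -0.10, P = 0.921
```

Reading the output: the dye leaves percent motile unchanged (paired t,
P = 0.40); two trait-difference PCs pass the Kaiser criterion
(eigenvalues 3.78 and 1.80 of 7). In the fertilisation comparison the
dye coefficient is indistinguishable from zero (Wald t₁₇ = 0.24,
P = 0.81); the base model is overdispersed (dispersion ≈ 3, extra-
binomial noise between trials), while adding an observation-level random
effect overcorrects to underdispersion (0.27) without changing the
conclusion — the characteristic pattern of this design.

A command-line interface mirrors the library:

```
spermcomp simulate-data --seed 3 --out out/
spermcomp motility      --input out/motility.csv --out out/
spermcomp fertilisation --input out/fertilisation.csv --out out/
spermcomp power         --config power.yaml --out out/
```

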