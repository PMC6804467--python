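# Methods

`synlink` models a family-based cytotoxicity study: a panel of cell lines
derived from pedigreed donors is exposed to two drugs singly and in
combination on 384-well plates, synergy is quantified per line by the
Chou–Talalay combination index, and the heritable component of synergy is
estimated and mapped by linkage. Everything below is implemented against
synthetic data with known ground truth; the generator's defaults define
the study conditions that the test suite and `scripts/acceptance.py`
exercise.

## Dose-response and synergy model

Cytotoxic response follows the median-effect law of the mass-action model.
With `Fa` the fraction of cells affected (dead) and `Fu = 1 − Fa` the
fraction unaffected,

    Fa / Fu = (D / Dm)^m

where `Dm` (µM) is the median-effect dose and `m` the sigmoidicity.
Taking log10 linearizes the law,

    log10(Fa/Fu) = m·log10(D) − m·log10(Dm),

so `m` and `Dm` are estimated per cell line × drug by ordinary least
squares on the monotherapy series (≥ 3 distinct doses; viabilities
strictly inside (0, 1)). A fit with nonpositive slope is marked invalid —
not an error — because the curve cannot be inverted.

For a combination observation at doses `(D1, D2)` with observed fraction
affected `Fa`, the expected monotherapy dose of drug *i* producing the
same effect is `E_i = Dm_i (Fa/Fu)^(1/m_i)` (both arms evaluated at the
single observed combination `Fa`), and the combination index is

    CI = D1/E1 + D2/E2.

CI < 1 indicates synergy (strong below 0.3, weak in [0.85, 1)), 1
additivity, > 1 antagonism. Because very large CI values arise from poorly
fit monotherapy curves rather than real antagonism, emitted CI is capped
at 5 with the raw value preserved for audit; invalid fits propagate as
*missing* CI with a reason, never as a capped number, since the cap
handles large finite values, not undefined ones. There is no lower bound.

## Synthetic data generator

**Pedigrees.** Disjoint nuclear families (father, mother, `children_per_family`
children; optionally a third generation). Default panel: 40 families of
2–4 children.

**Genotypes.** Gene dropping: founders are drawn from Hardy–Weinberg
proportions (default biallelic, frequency 0.5 — an idealised, maximally
informative SNP panel); each non-founder receives one recombinant gamete
per parent with Haldane crossover probabilities
`θ = (1 − exp(−2d/100))/2` between markers `d` cM apart, no interference.
Default genome: 4 chromosomes × 60 markers at 2 cM — a desk-scale
stand-in for a genome-wide microsatellite/SNP map. Simulated genotypes
contain no Mendelian errors by construction.

**Latent synergy trait.** `P = G + E`: the genetic value is an optional
biallelic QTL (additive allele effect solved from `2p(1−p)a² = V_qtl`,
read off the gene-dropped genotypes at the nearest marker) plus a
polygenic value — founders `N(0, Vg)`, non-founders midparent plus a
Mendelian-segregation deviate `N(0, Vg/2)` — and `E` is independent
`N(0, Ve)`. A line's true CI at every designed dose pair is
`exp(latent)` clipped to a configurable range (default [0.3, 2.0]): CI
stays positive, latent 0 maps to additivity, and heritability lives on
the log scale.

**Plates.** One cell line per 384-well plate, two replicate plates per
line (the runs of a duplicate-run design), each plate holding both
six-dose monotherapy grids, the six fixed-ratio combination pairs, and 16
vehicle plus 16 negative-control wells, everything in quadruplicate. Dose
grids are two-fold series spanning `Dm/8` to `4·Dm`; grids bracket the
median-effect dose from below so that combination wells — which respond
more strongly than either monotherapy — stay inside the assay's dynamic
range. Per line, `Dm` is lognormal around the population value with a
between-line CV (default 0.3; curve shape `m` is shared). Combination
wells are placed on the response surface where the line's true CI is
attained: the generating `Fa` solves `D1/E1(Fa) + D2/E2(Fa) = CI_true`
(unique root, the left side being strictly decreasing). RFU is an affine
map of viability between the negative-control level (500) and the
vehicle level (10 000) plus Gaussian noise (default sd 150 RFU ≈ 1.6% of
the dynamic range); deviant wells are multiplied ×5 at a configurable
rate, and dead plates are redrawn Uniform(0, 1500) so the 90th-percentile
filter must catch them.

What the generator does **not** emulate: spatial plate gradients and edge
effects, batch/incubator drift between runs, non-median-effect response
shapes, genotyping error, allele-frequency spectra or linkage
disequilibrium, and dose-dependent synergy profiles (a line's true CI is
constant across its dose pairs). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to structured real-world artifacts.

## Plate quality control

Five stages, in order:

1. **Quadruplicate screen.** If the CV (sd/mean) of a quadruplicate
   exceeds the threshold (default 0.3), the single value whose removal
   minimizes the remaining CV is replaced by the mean of the other three,
   provided that reduced CV passes; otherwise (≥ 2 deviants) all four are
   replaced by their own mean. "Mean across samples" is read as the mean
   of the quadruplicate itself, keeping the repair local to the
   condition.
2. **Plate filter.** A plate whose 90th-percentile raw RFU
   (linear-interpolation percentile) falls below 2000 is removed as mass
   cell death. Flags recorded on a removed plate are discarded with it.
3. **Control cleanup.** Vehicle and 10% DMSO negative controls are
   cleaned separately by an iterative flag-and-replace loop: regress on
   well index, flag |externally studentized residual| > 3, replace the
   worst offender with the leave-one-out regression prediction, refit;
   stop when clean or after 10 iterations. The leave-one-out prediction
   is used (rather than the full-fit fitted value) because it matches the
   externally studentized residual that triggers the flag and is not
   dragged toward the outlier it replaces.
4. **Normalization.** `viability = (RFU − N̄)/(V̄ − N̄)`, clipped to
   [ε, 1−ε] with ε = 0.005 so the median-effect log transform stays
   finite; `V̄ ≤ N̄` marks the plate unusable.
5. **Dose-response screen.** The same flag-and-replace loop within each
   single drug, run on the median-effect linearized scale
   (`log10(Fa/Fu)` vs `log10 D`), under which a clean series is exactly
   linear — on the raw viability scale a clean sigmoid has structural
   curvature and its endpoints would be "corrected". Combination series
   are excluded: with unequal sigmoidicities they are not log-linear even
   when clean, and their wells are already screened at stage 1. A
   replacement that would not change the value (e.g. a clip-saturated
   endpoint) is skipped, which keeps QC idempotent on clean data.

Replicate runs are averaged at the normalized-viability level after QC,
giving one dose-response series per line × condition before fitting —
one CI per line per dose pair. Exact near-fits (SSE at floating-point
noise level) are treated as clean rather than studentized.

## Heritability

Broad-sense heritability is reported as the variance-component ratio
`H² = Vg / (Vg + Ve)` from the model `trait ~ N(μ·1, 2Φ·Vg + I·Ve)` per
family block, with Φ the exact recursive kinship matrix (no dominance or
household components — with pedigree data of this structure this is what
standard pedigree variance-component software estimates). The likelihood
is maximized over log-variances by multi-start L-BFGS-B (5 seeded
starts), the mean profiled out by GLS and the `Vg → 0` boundary checked
explicitly; families with identical kinship blocks share one
eigendecomposition. Missing trait values drop the individual; a sample
with no related phenotyped pair returns `converged=False` with `H²`
missing rather than a number. Per-dose heritability tables select the
max-H² dose, ties breaking toward the earlier dose (logged); duplicate
runs enter as their mean because QC has already averaged them.

## Linkage

The scan replaces an exact whole-pedigree inheritance-vector likelihood
with a sib-pair decomposition, appropriate because the panels decompose
into nuclear families and regression-based sib-pair linkage is robust to
non-normal phenotypes:

* **Multipoint IBD.** Per full-sib pair, a hidden chain over the 16
  inheritance-vector states (which parental haplotype each sib received
  from each parent) is evaluated by forward–backward along each
  chromosome with Haldane transitions (each meiosis indicator flips
  independently with probability θ). Emissions use parental genotypes
  when typed and integrate exactly over Hardy–Weinberg genotypes when a
  parent is missing; a Mendelian-inconsistent marker is dropped for that
  pair (logged). States collapse to IBD counts {0,1,2};
  `π̂ = P1/2 + P2`. Uninformative data leave the prior (¼, ½, ¼), π̂ = 0.5.
* **Haseman–Elston regression.** At each grid position (default 1 cM) the
  squared sib-pair trait difference is regressed on π̂; linkage drives the
  slope negative and the one-sided evidence is `LOD = t²/(2 ln 10)` for
  negative slopes, else 0. Positions with fewer than 20 informative pairs
  or no IBD variation are skipped. All distinct sib pairs enter without a
  within-sibship correlation correction (classic HE; a caveat for large
  sibships, where the nominal t is overdispersed). Peaks above LOD 3 are
  reported with their 1-LOD support interval.

## Validation experiments and problem sizes

`scripts/acceptance.py` recomputes, from scratch at each run: sham-
combination additivity (a compound against its own relabelled dilution,
CI = 1 to 1e-6); the CI cap; the dead-plate boundary by bisection; exact
median-effect recovery; median absolute CI error under 3%-of-range RFU
noise over 100 lines (~0.04); mean H² estimates over 20 replicate
150-family panels for generators at 0.3 and 0 (~0.27 and ~0.03 — ML at
the `Vg ≥ 0` boundary biases the null estimate slightly upward and the
0.3 estimate slightly downward at this panel size); linkage power and
null calibration; and QC deviant recall (~99%).

The linkage power experiment uses 600 nuclear families of 3 children
(1800 sib pairs), the panel size at which squared-difference HE reliably
places the top peak on the QTL chromosome for a locus carrying 30% of
trait variance (19–20 of 20 seeds; ~45% of seeds at a 360-pair panel).
The null calibration runs 50 seeds at the same scale. These sizes are the
package's choice of a well-powered desk-scale design for the method being
demonstrated.

## Numerical choices

* Log base 10 throughout the median-effect algebra; the slope is
  base-invariant and `Dm = 10^(−intercept/m)`.
* Percentile convention: linear interpolation, making the 2000-RFU plate
  boundary bit-reproducible.
* The generating-`Fa` root solve uses Brent's method on logit(Fa) in
  [−60, 60].
* Forward–backward posteriors are renormalized each step; posteriors sum
  to 1 within 1e-10.
* Variance-component convergence: L-BFGS-B `ftol` 1e-8 on the profile
  log-likelihood; `Vg` below `1e-8·Vp` snaps to the boundary.
* Determinism: every stochastic routine takes an explicit seed and uses
  its own `numpy` Generator; identical seeds and configs give
  byte-identical outputs.

## Known limitations

* The CI estimate saturates when combination viability hits the ε-clip:
  strongly synergistic lines (true CI near 0.3) at the top dose pairs can
  read slightly high. This mirrors a real assay's dynamic-range limit.
* Sib-pair HE discards information in larger pedigrees (no Kong–Cox /
  inheritance-vector likelihood over extended families) and loses power
  relative to variance-component linkage; the desk-scale power experiment
  compensates with panel size.
* `H²` here is the additive variance-component ratio; dominance and
  shared-environment components are not modelled.
* No multiple-testing adjustment beyond the LOD 3 reporting threshold.
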