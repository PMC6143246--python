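# Methods

This note records the statistical model behind `egobp`, the conventions the
implementation commits to, how the synthetic-cohort generator was
calibrated, and what the package's tests do and do not establish.

## Study design being modelled

Each participant ("ego") names exactly 30 alters and rates, for all 435
unordered alter pairs, how likely the two are to talk to each other on a
1–5 scale.  Ratings of 4 or 5 define a tie; the thresholded graph is the
ego's personal network.  Participants are genotyped at three adjacent *ACE*
markers — rs4313 (C/T), rs4337 (C/G) and the intron-16 *Alu* insertion
(I/N) — which span one strong-LD block carrying four haplotypes: hap1
(T-G-N), hap2 (C-G-N), hap3 (T-G-I), hap4 (T-C-I).  Blood pressure is the
mean of the last two of three oscillometric readings, with +10/+5 mmHg
added to SBP/DBP of participants on antihypertensive medication (the
standard additive treatment correction; a sensitivity mode instead keeps
raw readings and carries medication as a covariate — both are implemented).

## Network measures

All graphs are undirected and unweighted.

* **Betweenness** is unnormalized with fractional shortest-path counting,
  B(v) = Σ_{{s,t}: v∉{s,t}} σ_st(v)/σ_st, computed by Brandes' dependency
  accumulation.  The implementation runs all 30 sources simultaneously in a
  level-synchronous matrix form (frontier advance and dependency sweep as
  n×n products), which is algebraically identical to the per-source
  algorithm and is verified against exhaustive simple-path enumeration on
  all test graphs with ≤ 8 nodes and against networkx.
* **Mean distance** is the mean geodesic distance over *reachable*
  unordered pairs.  Unreachable pairs are excluded rather than penalized:
  no convention for fragmented personal networks is documented for the
  interview software this design derives from, and the exclusion convention
  preserves the exact identity Σ_v B(v) = Σ_reachable pairs (d−1), which
  the test suite checks on hundreds of random graphs.  A penalized variant
  (unreachable pairs scored as n = 30) is available via configuration.
* **"Most close"** uses harmonic closeness C(v) = Σ_u 1/d(v,u), which is
  well defined on fragmented graphs (isolated alters are common);
  classic closeness is not used.  **"Most distant"** is the maximum farness
  (mean reachable distance), isolates excluded from candidacy.  All argmax
  ties break to the lowest alter index, so positions are deterministic.
* **% central positions family** counts each of the three positions
  separately even when one node holds several (denominator fixed at 3).
* Mean distance on an edgeless network is undefined (missing value with a
  warning, and the ego drops out of complete-case modelling).

Distances of 1 mean everyone talks to everyone; with the default generator
essentially every network has edges and edgeless handling is exercised only
in tests.

## Haplotype phasing and LD

Frequencies are estimated by the Excoffier–Slatkin EM algorithm on unphased
multilocus genotypes: the E-step distributes each individual over the
diplotypes compatible with its genotype proportional to f(h1)·f(h2)
(doubled when h1 ≠ h2), the M-step re-estimates frequencies from expected
counts.  Initialization is uniform over all compatible haplotypes,
convergence is Δlog-likelihood < 1e-8 (cap 1,000 iterations; the
log-likelihood path is stored and is non-decreasing by construction of EM).
A genotype missing at some markers simply enlarges its compatible set;
individuals missing every marker are excluded and logged.  At three
biallelic markers in samples of this size the EM maximum-likelihood
solution coincides with what a Bayesian coalescent phaser would report;
the test suite verifies EM reaches the global likelihood maximum found by
an independent multi-start numerical optimizer.

Phasing is summarised per individual as the posterior-best diplotype
(lexicographic tie-break).  Two regression codings are provided, because a
printed one-haplotype-per-person grouping does not determine its rule:

* **dosage** (default): 0/1/2 counts of hap2, hap3, hap4; hap1 is the
  reference and is omitted — coefficients read as mmHg per haplotype copy;
* **categorical** (rarest-first): each individual is assigned the
  lowest-frequency named haplotype they carry, which reproduces
  mutually-exclusive group sizes of the kind printed in the source design
  (with default frequencies the priority is hap3 > hap2 > hap1 > hap4).
  This grouping also feeds the Tukey–Kramer contrasts.

Pairwise LD uses D = p_AB − p_A p_B, Lewontin's D′ = |D|/D_max and
r² = D²/(p_A p_a p_B p_b); a monomorphic marker leaves LD undefined.
Blocks are maximal runs of contiguous markers whose *all* pairwise D′ clear
0.8 (greedy left-to-right).  This deliberately simplifies the
confidence-interval block definition of standard LD-browser software: the
analysis only needs the strong-LD block containing the three markers, which
any reasonable rule reproduces.

## Regression models and selection

For each response (SBP, DBP), with age, BMI and sex (male = 1, female = 2)
always included:

* base = covariates; genetic = base + haplotype dosage block;
  network = base + network measures surviving the keep rule;
  optimal = selection over [haplotype block, then each network measure] in
  that order, starting from base.
* The four network measures enter square-root transformed (proportions on
  the [0,1] scale, consistent with coefficient magnitudes near 9–16 per
  unit).
* Keep rule: a candidate stays iff AIC strictly decreases **and** adjusted
  R² strictly increases; ties lose.  The haplotype dosages move as one
  block; their individual p-values are reported but never drive selection.
* AIC = n·[ln(2π·RSS/n) + 1] + 2(k+1), the full Gaussian profile
  likelihood with σ counted as a parameter (the convention of mainstream
  statistical software).  Absolute AICs are therefore comparable across
  implementations that use the same convention; selection depends only on
  differences, where the constants cancel.
* Constant design columns (e.g. a haplotype absent from a small cohort) are
  dropped with a logged warning instead of failing on a singular design.
* Model comparisons use the extra-sum-of-squares F test; the multiple-test
  threshold is Bonferroni α/m with m = 5 (one haplotype block + four
  network measures → 0.05/5 = 0.01; the alternative reading 1×4 = 4 would
  give 0.0125 and is not used).
* Tukey–Kramer: q_ij = |m_i − m_j| / √(MSW(1/n_i + 1/n_j)/2), adjusted p
  from the studentized-range distribution with (k, N−k) parameters
  (`scipy.stats.studentized_range`; for k = 2 this reduces exactly to the
  pooled t-test via q = t√2, which the tests verify).  Singleton groups are
  allowed (Kramer correction).
* An interaction/change-point screen for any focal term adds focal×term
  products one at a time (nested F), and scans a single threshold indicator
  over a grid of observed focal values (≤ 32 quantile-thinned cuts),
  flagging by a χ²₁ likelihood-ratio reference.  The scan p-value is
  anti-conservative (maximum over cuts); it is a screening flag, not a
  calibrated test.

Selection caveat: single-pass forward selection tests each candidate once,
at the moment it is reached.  When candidates are strongly correlated
(see generator limitations below) a generating variable whose effect is
masked until a later variable enters can be missed, and a correlated proxy
kept in its place.  The full decision trace (AIC and adjusted R² before and
after every candidate) is emitted precisely so such paths are auditable.

## Synthetic-cohort generator

Defaults reproduce the published structure of the cohort the design comes
from; they are study conditions, not tuning knobs.

* Demographics: 66.7% female; age ~ N(41, 11.9²) truncated to [25, 65]
  (truncation lifts the realized mean to ≈ 42.3); BMI ~ N(28.8, 7.4²) for
  men, N(34.2, 10.3²) for women, floored at 15 kg/m²; 31% medicated
  (independently of BP — a simplification, see limitations).
* Genetics: diplotypes are two i.i.d. draws (Hardy–Weinberg) from
  (hap1, hap2, hap3, hap4) = (0.15, 0.07, 0.005, 0.775), chosen so
  rarest-first categorical group sizes approximate a 30/17/1/90 split of
  138.
* Networks: per ego a family share s ~ N(0.503, 0.255²) truncated to
  [0, 1]; per-alter family flags Bernoulli(s); one latent tie per pair with
  class probabilities (both-family 0.52, mixed 0.0003, both-non-family
  0.265); ratings are then drawn conditionally on the tie (4/5 with
  probability 0.4/0.6 given a tie; 1/2/3 with 0.5/0.3/0.2 otherwise), so
  thresholding at 4 recovers the latent graph exactly and graph-level
  calibration is independent of rating noise.  The three tie probabilities
  were calibrated by simulation so that 2,000-ego study means land on the
  published mean betweenness 6.9 and mean distance 1.76 (asymptotic values
  ≈ 6.91 and 1.757 across seeds); family share hits 50.3% by direct
  parameterization.  The near-zero mixed probability is forced by the
  betweenness–distance identity: appreciable family/non-family bridges act
  as brokers and inflate mean betweenness far above 6.9 at any density
  compatible with mean distance 1.76.
* Blood pressure: latent SBP/DBP are linear with the published
  optimal-model coefficients (e.g. SBP: age 0.55, BMI 0.74, sex −14.05,
  hap2 −14.75, hap3 −32.42, hap4 −13.70, √betweenness 2.59, √%central
  family 9.39) plus N(0, 17²) / N(0, 12²) residuals; intercepts 118.3/54.4
  set the population means at ≈ 129.5/81.9 mmHg (realized 129.9 ± 21.5 /
  82.1 ± 13.7 at n = 6,000, against the published 129.5 ± 21.2 /
  81.9 ± 13.4).  Medicated participants' *observed* pressure is generation
  minus 10/5, so the phenotype correction restores the model scale.  Three
  readings are emitted as observed + N(0, 3²) each, rounded to 0.1 mmHg
  (typical within-visit oscillometric variability and monitor precision).
* Reproducibility: one root seed; every stage, column and ego draws from
  its own counter-derived substream with single-draw inverse-CDF sampling,
  so row k of every table depends only on (seed, k) — extending a cohort
  never changes existing rows, and regeneration is byte-identical.

### What the generator does and does not emulate

It reproduces the published marginal structure (demographics, haplotype
frequencies, network means and dispersions, BP means/SDs and effect sizes)
and a family-driven community structure in the networks.  It does **not**
emulate: assortative or geographically structured tie formation beyond the
family/non-family dichotomy; any dependence of medication use on BP or age;
missing data (tables are complete unless corrupted deliberately);
measurement properties of the rating scale beyond the tie dichotomy; or
linkage to a wider marker panel.  One consequence matters for method
evaluation: because a single family-share variable drives both composition
and structure, the four network measures are more collinear here than in
the field data (√betweenness vs √distance r ≈ 0.90; √%family vs √%central
family r ≈ 0.81, versus a published 0.43 for the untransformed pair).
Passing tests therefore demonstrate correctness of the algorithms and
honest behaviour of the selection procedure *under strong collinearity*,
not that forward selection would recover the same terms in the field data.

## Test strategy and problem sizes

Oracles are independent of the implementation: exhaustive simple-path
enumeration (graphs ≤ 8 nodes), networkx, closed-form LD arithmetic,
direct numerical maximization of the genotype likelihood, the q = t√2
identity, and hand-computed regression sums.  Simulation-based checks use
2,000-ego studies (100 replicates for parameter recovery, single studies
for calibration), sizes at which Monte-Carlo error on the calibrated means
is a few per mille to a few percent while the whole suite stays in the
minutes range.  Parameter recovery refits the generating model on the
pipeline's own analysis table (phased dosages, corrected BP), so it
includes phasing and phenotype processing, not just OLS.

## Known limitations

* Forward selection is single-pass (no backward sweeps), mirroring the
  modelled design; under the generator's collinearity it keeps correlated
  proxies at realistic rates (the AIC keep rule retains a pure-noise 1-df
  candidate with probability ≈ 0.157 by the χ²₁ > 2 exceedance), so the
  "optimal" term set is a noisy estimate at any realistic sample size.
* The change-point screen's p-value is not corrected for scanning.
* The EM phaser targets k ≤ 5 biallelic markers; it is not a genome-scale
  tool and does no imputation beyond marker-level missingness.
* The D′-threshold block rule is a simplification; block boundaries away
  from the strong-LD regime should not be over-interpreted.
* Medication is simulated independently of BP; the +10/+5 correction is
  exact by construction in synthetic data, which is a best case relative to
  field conditions.
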