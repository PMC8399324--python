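# Methods

## The problem

In vitro-produced (IVP) cattle embryos are cultured singly for 24 h in
protein-free medium before transfer; the spent culture medium (CM) carries a
metabolic footprint of the embryo. Whether a CM metabolite predicts pregnancy
depends strongly on context — cryopreservation, bull breed, culture
supplement (BSA vs BSA + FCS), developmental stage at the start (0 h: morula
M, early blastocyst EB, blastocyst B) and end (24 h: expanding ExB, fully
expanded FEB) of single culture, and embryo age (Day 7/8). `embryocm`
implements a screening strategy that embraces this heterogeneity: instead of
one global model, it tests every metabolite inside every *block* (a
fixed-factor stratum crossed with a pregnancy endpoint: Day-40, Day-62 or
birth) and then weights the winners by how much of the embryo population
each block represents.

## Preprocessing

Raw aligned peak areas (duplicate injections per sample) run through a fixed
order, recorded in a JSON sidecar:

1. **Replicate averaging** — arithmetic mean of non-missing injections.
2. **Consistency filter** — a feature is kept if observed in ≥ 80% of the
   samples of at least one comparison group (default groups: the pregnancy
   outcome classes). Retention is monotone in the threshold.
3. **Missingness cap + imputation** — features missing in > 25% of samples
   are dropped; remaining holes are filled by iterative random-forest
   regression on the other features (missForest-style,
   `IterativeImputer(RandomForestRegressor)`), with imputed values clipped to
   each feature's observed range. Deterministic given the seed.
4. **Total-intensity normalization** — each sample is scaled so its total
   equals the grand mean of sample totals. Each blank is then carried onto
   the sample scale with the mean normalization factor of its own batch's
   samples: a blank's raw total is not comparable to sample totals (it
   lacks the embryo-released material), so balancing blanks to the sample
   grand mean would systematically over-subtract and bias net values
   negative.
5. **Blank subtraction** — each sample minus its culture-batch blank
   (one blank per transfer-round × culture batch). Negative net values are
   kept: they are consumption of medium constituents.

Filtering precedes imputation so the imputer never spends effort on features
that are discarded anyway; normalization precedes subtraction, which means a
residual sample-vs-blank scale mismatch can attenuate small consumption
signals (see Limitations).

## The two-level block screen

Blocks are enumerated as the Cartesian product of {each factor's levels +
free} with a stage-constraint whitelist (0 h: singletons, EB+B, free; 24 h:
singletons, free), crossed with the three endpoints, keeping blocks with at
least `min_class = 3` samples in both outcome classes and collapsing
constraint tuples that resolve to identical sample sets onto the coarsest
one. Screening a block never depends on other blocks.

Within a block, per feature:

* **Level 1 (volcano)**: pass iff |log2 FCh| ≥ 1 (fold change ≥ |2|) — or
  the qualitative sentinel — and min(p_t, p_KW) < 0.10, where p_t is the
  two-sample t-test (one-way ANOVA with two groups) and p_KW the
  Kruskal–Wallis test; p < 0.05 is flagged "significant", [0.05, 0.10)
  "tendency".
* **Level 2 (ROC)**: empirical rank ROC-AUC (Mann–Whitney concordant-pair
  fraction, half credit for ties, direction-free: max(A, 1−A) ∈ [0.5, 1])
  must exceed 0.700 with t-test p < 0.10. Blocks with fewer than 12 samples
  and AUC ≥ 0.850 are admitted up to p < 0.15 and flagged as small-n
  exceptions.

**Fold change on the net scale.** With both group means positive, LogFCh =
log2(mean_P/mean_O); with both negative (mutual consumption), the ratio of
absolute means. When the classes straddle zero — one class effectively at
blank level — the ratio is undefined and the sentinel ±99.000 is reported,
signed by (mean_P − mean_O): a "qualitative" difference, which automatically
satisfies the fold-change gate. Log base 2 is used so the FCh ≥ |2| gate is
exactly |LogFCh| ≥ 1. No multiple-testing correction is applied inside the
screen (raw p-values plus test counts are reported); family control happens
only in the whole-dataset models below.

## Impact weighting and series

The *impact* of a block is the percentage of the embryo population in its
culture × stage stratum, taken from a stage-abundance table built on a larger
reference metapopulation (default n = 1114 virtual embryos). Blocks free of
culture and stage constraints carry impact 100; culture-constrained,
stage-free blocks carry the culture total (100); free-culture blocks with
stage constraints pool metapopulation counts across cultures. *Predicted
coverage* of a single biomarker = AUC × impact (percent); singles with
coverage ≥ 70% are reported.

A *series* is a set of member blocks sharing endpoint, cryopreservation,
breed, culture and age whose stage strata are pairwise disjoint; its
*combined coverage* is the sum of member coverages. All disjoint stratum
sets are enumerated (depth-first with overlap pruning over the small stage
lattice) and, per series signature, the member-metabolite assignment
maximizing combined coverage is selected (ties: fewer members, then
lexicographic metabolite ids); series with combined coverage > 80% are
reported. Because disjoint strata partition the population, combined
coverage of a full partition never exceeds 100.

## Whole-dataset reports

Candidate metabolites from the screen are re-tested over the entire cohort
with ordinary least squares (intensities are continuous, so the linear model
uses a Gaussian identity link) on all fixed factors plus the endpoint term;
the endpoint coefficient's Wald p is reported for the binary endpoints, and
an F-test of the three-level outcome (term birth / post-Day-40 loss / open)
for the miscarriage contrast. Bonferroni control is applied over the
candidate family m at levels 0.05 and 0.10. The package also produces
taxonomy × endpoint × cryo-status block tallies, a metabolite × endpoint
heatmap matrix ranked by total blocks, a binned AUC-vs-sample-number summary
with Pearson correlations (p-values on a ×10 scale for visual comparability;
a constant series is reported as r = 0), and descriptive pregnancy-rate
tables where recipients flagged as lost before term are excluded from the
birth denominator only.

## The synthetic cohort generator

No public CM cohort of transferred embryos exists at this design, so the
generator emulates one:

* **Design margins** — 84 transfers by default: 28 fresh (17 BSA, 11 FCS,
  Day-7) and 56 frozen (30 BSA Day-7, 8 BSA Day-8, 18 FCS Day-7); margins are
  honoured exactly. Breed, bull (7 levels), sex and stages are drawn per
  sample (stage probabilities M/EB/B = 0.2/0.4/0.4, ExB/FEB = 0.4/0.6; the
  24 h stage is always developmentally later than the 0 h stage).
* **Endpoints** — a monotone chain: P(Day-40) = 0.60,
  P(Day-62 | Day-40) = 0.95, P(birth | Day-62) = 0.80, approximating the
  descriptive rates of a cohort of this type, so birth ⇒ Day-62 ⇒ Day-40
  holds by construction and miscarriage = Day-40 positive, birth negative.
* **Intensities** — log-normal net signals (log2 magnitude U(8, 14), noise
  SD 0.5 log2 units). 30% of features are medium constituents with blank
  levels 2^14–2^18 and *consumed* (net-negative) signals sized as 2–18% of
  the blank pool — an embryo draws a modest fraction of a constituent, so
  even a 4-fold planted boost never exceeds the blank. A bull random
  intercept (SD 0.5 log2) acts on 25% of features. Measured raw signal =
  batch blank + net, floored at zero.
* **Blanks and batches** — one blank medium record per (round × culture)
  batch, rounds of 4 embryos, with 10% log-scale batch wobble of blank
  levels (which cancels in subtraction since samples ride on their own
  batch blank).
* **Replicates and missingness** — two injections at 2% analytical CV;
  values below the global 2% detection-limit quantile are censored (MNAR)
  plus 1% MCAR dropout.
* **Planted effects** — per-stratum pregnancy effects in two modes: *shift*
  (a log2 offset of the net magnitude, applied to whichever class gives the
  requested contrast sign) and *qualitative* (the low class at blank level,
  net ≲ 0, the other releasing — guaranteeing opposite-sign group means so
  the ±99 sentinel fires; such signals are forced onto constituent features,
  since absence is only observable against a nonzero blank). A truth ledger
  records each planted feature's exact stratum and endpoints.
* **Impact table** — multinomial stage-cell counts of 1114 virtual embryos
  per culture; percentages sum to exactly 100 within culture.

What the generator does **not** emulate: chromatographic drift and QC-based
correction, correlated metabolite modules (features are independent given
bull), recipient effects, round-level batch effects beyond the blank, or
realistic m/z–RT structure (annotations are exercised with constructed
libraries). Passing recovery/calibration tests therefore demonstrates the
pipeline's statistical behaviour under its own assumptions, not performance
on real instrument data.

## Numerical choices and validation

* Rank AUC via midranks (`scipy.stats.rankdata`), cross-checked against a
  brute-force pair count on 1000 random instances.
* Degenerate screens: two identical constant groups get p = 1 and fail;
  both-zero means yield a flagged NaN fold change.
* Identical-resolution blocks collapse to the fewest-constraints
  representative; enumeration is validated against a brute-force grid.
* Calibration: under the global null (no planted effects) the level-1 pass
  rate over 200 cohorts × 20 features stays within 3 Monte-Carlo SEs of the
  nominal 10% (the fold-change gate makes it far lower in practice).
* Recovery: planted 2-log2-unit shifts with ≥ 8 samples/class are recovered
  in their planted blocks in ≥ 90% of 30 seed × effect combinations, through
  the full pipeline including imputation and normalization.
* Determinism: one master seed drives generation, imputation and the run
  manifest; a rerun is byte-identical. Problem sizes used in the shipped
  validation runs (20–40 features, 24–84 samples, 200 null cohorts, 5
  recovery cohorts) were chosen to exercise every code path at desk scale.

## Known limitations

* Normalizing before blank subtraction (the pipeline's fixed order) leaves a
  sample-vs-blank scale mismatch of order (s_sample − s_blank) × blank that
  can attenuate consumption signals that are small relative to the blank
  pool; this is a property of the procedure, not of the implementation.
* The 0.25 "threshold" of the imputer is read as a per-feature missingness
  cap (the alternative — a forest hyperparameter — is not adopted).
* The small-n exception (AUC ≥ 0.850, p < 0.15, n < 12) is a convenience
  rule for thin strata; its hits are flagged and should be treated as
  supporting evidence only.
* Series optimization is exhaustive over the stage lattice, which is small
  by design; it does not scale to arbitrary stratum systems.
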