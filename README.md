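# embryocm

Block-stratified biomarker discovery in spent embryo culture-medium (CM)
metabolomics.

Whether a CM metabolite predicts pregnancy after embryo transfer depends on
the conditions the embryo was produced under — cryopreservation, bull breed,
culture supplement (BSA vs BSA + FCS), developmental stage at the start
(morula M, early blastocyst EB, blastocyst B) and end (expanding ExB, fully
expanded FEB) of the 24 h single-culture step, and embryo age. `embryocm`
screens every metabolite inside every *block* (a fixed-factor stratum
crossed with a pregnancy endpoint: Day-40, Day-62, birth) and weights the
winners by the share of the embryo population each block represents, so a
lab can assemble condition-specific biomarker panels rather than search for
one universal marker.

For metabolomics analysts and embryologists working with untargeted LC-MS
feature tables of single-embryo culture medium; everything runs from a raw
aligned feature table (TSV) plus a sample annotation sheet, blank-medium
records and a stage-abundance table.

## Method

* **Preprocessing**: duplicate-injection averaging → consistency filter
  (feature observed in ≥ 0.8 of at least one outcome group) → 0.25
  missingness cap + iterative random-forest imputation → total-intensity
  normalization → subtraction of the matched culture-batch blank. Net
  values may be negative: consumption of a medium constituent.
* **Two-level screen** per block × feature:
  level 1 (volcano) — fold change FCh ≥ |2| and min(t-test, Kruskal–Wallis)
  p < 0.10 (p < 0.05 "significant", otherwise "tendency"); level 2 (ROC) —
  empirical rank AUC > 0.700 (Mann–Whitney concordant-pair fraction,
  direction-free) with t-test p < 0.10, plus a flagged small-block
  exception (n < 12, AUC ≥ 0.850, p < 0.15). When one outcome class sits at
  blank level the fold-change ratio is undefined and the sentinel
  **±99.000** is reported (a "qualitative" difference).
* **Coverage**: a block's *impact* is the percentage of the embryo
  population in its culture × stage stratum (from a reference
  metapopulation); *predicted coverage* = AUC × impact (singles gate:
  ≥ 70%). A *series* combines stage-disjoint blocks sharing endpoint /
  cryo / breed / culture / age; *combined coverage* = Σ AUC·impact over
  members (gate: > 80%), optimized exhaustively over the stage lattice.
* **Cohort-level reports**: OLS endpoint models over all fixed factors with
  Bonferroni control over the candidate family, taxonomy/endpoint block
  tallies, an AUC-versus-sample-number summary, and descriptive
  pregnancy-rate tables.
* **Synthetic cohorts**: a first-class generator
  (`embryocm.synthetic`) emulates the full study — log-normal intensities,
  blank-relative consumption/release, bull random effects, detection-limit
  censoring, duplicate injections, and per-stratum planted effects
  (log2 shifts or qualitative regimes) with a planted-truth ledger — so the
  whole pipeline is testable without any instrument data.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a cohort with four planted biomarkers and run every stage:

```sh
embryocm all --outdir demo_run --seed 42 --n-features 40 --n-planted 4
# pipeline complete: 778 blocks, 1168 hits, 190 singles, 85 series
```

The 84 simulated transfers honour the default design margins (28 fresh /
56 frozen across BSA and FCS cultures). `singles.tsv` mirrors the
single-biomarker report — here the planted feature F0001 separates
pregnant from open embryos perfectly in its frozen/BSA block:

```
feature_id  AUC  LogFCh endpoint   cryo culture  N_P  N_O  impact  predicted
     F0001  1.0   2.262      D40 frozen     BSA   11    8   100.0      100.0
```

AUC 1.000 on a block carrying 100% of the population predicts 100% of
pregnancies under those conditions; `LogFCh 2.262` means ~4.8-fold higher
net signal in CM of pregnant-outcome embryos. Of the 1168 hits, 155 carry
the ±99.000 sentinel — metabolites effectively absent (at blank level) in
one outcome class. `series.tsv` shows combined panels; e.g. two
stage-disjoint frozen blocks (ExB vs FEB at 24 h) jointly cover

```
series feature_id endpoint   cryo stage24h  impact  predicted  combined
    26      F0018      D40 frozen      ExB  40.844     40.844    97.809
    26      F0015      D40 frozen      FEB  59.156     56.965    97.809
```

i.e. 97.8% of frozen embryos get a correct pregnancy call from one of the
two metabolites, each applied in its own stage stratum.
`pregnancy_rates.tsv` holds the descriptive endpoint rates per
cryo × culture × age group, e.g. `fresh BSA 7: n=17, D40 9 (52.9)`.
Re-running with the same seed reproduces every output byte for byte
(`manifest.json` records the seed, configuration hash and row counts).

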