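# Methods

## Scope and model of the data

`larvatox` implements the statistical analysis of a zebrafish (*Danio
rerio*) developmental-toxicity screen for three endocrine-disrupting
chemicals (triclosan, triclocarban, 4-nonylphenol) at nanomolar exposures,
covering four stages:

1. **Larval photomotor-response (LPR) QC** of per-larva locomotion traces
   recorded over a 24-minute alternating light/dark protocol;
2. **Behavioral group statistics** (one-way ANOVA + Tukey HSD) on per-larva
   phase means;
3. **Abnormality/mortality endpoint screening** (chi-square with Bonferroni
   pairwise comparisons, and a 100%-mortality evaluability gate);
4. **DEG accounting** — a significance filter on per-gene differential
   expression results plus count and set-overlap bookkeeping.

A seeded synthetic-data module generates all three input kinds with known
ground truth, so the full pipeline is testable without any external data.

## Photoperiod protocol and QC rules

The assay alternates 3-minute light and dark phases for four light-dark
cycles (24 min) with a 6-second integration bin: 8 phases × 30 bins = 240
bins per larva. Healthy larvae show scototaxis-driven dark hyperactivity:
they move substantially more in dark than in light.

QC evaluates three per-trace rules; a trace is excluded if any fires:

* **Light serial-exceedance.** Over a trace's own light-phase bins, compute
  the Tukey fence `T = Q3 + k·IQR` with `k = 1.5`. Flag when 2 consecutive
  light bins — both past a 60-second per-phase burn-in — strictly exceed T.
  The burn-in skips transition startle artifacts; with 6-s bins,
  "elapsed time at bin end > 60 s" skips exactly the first 10 bins of each
  light phase. The per-phase interpretation (rather than 60 s of the whole
  session) was chosen because light↔dark transitions perturb behavior at
  every phase start, not just the first; it is configurable
  (`QCThresholds.light_burn_in_s`).
* **Dark below-median.** Flag when 2 consecutive dark bins each fall
  strictly below the median of the trace's light bins — a larva whose dark
  activity collapses below its own light level.
* **Light:dark ratio.** Flag when mean(light)/mean(dark) ≥ 0.9, boundary
  inclusive. A zero dark mean makes the ratio undefined; such a larva is
  treated as a non-responder (flagged, with a warning).

Numerical choices: quantiles use linear interpolation between order
statistics (numpy default) and are declared in the QC report; "serial"
means adjacent bin indices within the same phase (runs never span a phase
boundary); all inequalities on data values are strict except the ratio
cutoff, which is inclusive. Q3/IQR and the light median are computed
per-trace (each larva is its own reference population), which makes every
rule a function of that trace alone; QC is therefore idempotent,
order-independent, and invariant to cohort composition. A pooled-population
alternative is intentionally not implemented as a default behavior.

## Behavioral statistics

The unit of analysis is the per-larva phase mean (cm/bin averaged over all
light bins, and separately all dark bins), avoiding pseudo-replication of
bins. Light and dark are separate analysis families with no cross-phase
multiplicity correction. Groups are compared by one-way ANOVA followed by
Tukey's HSD over all pairs (statsmodels), reported filtered to
each-group-vs-control with a hypo/hyper direction label, α = 0.05.
Shapiro–Wilk is exposed as `normality_check` (3 ≤ n ≤ 5000) and is purely
diagnostic — locomotion data are typically non-normal, and the ANOVA is run
regardless, matching standard practice in this assay. No non-parametric
fallback is added.

## Endpoint screening statistics

Screening tables hold affected/total counts per endpoint (mortality,
unhatched, skeletal deformities, uninflated swim bladder, yolk-sac edema,
cardiac edema, total abnormalities) × concentration × timepoint
(24–120 hpf). Per endpoint slice, the global test is an uncorrected Pearson
chi-square on the 2 × k table (df = k − 1); Yates continuity correction is
off by default (appropriate at n = 150 per group) but exposed as a flag.
Each non-control concentration is compared to control by a 2 × 2 chi-square
with Bonferroni adjustment `p_adj = min(1, m·p)` over the m non-control
comparisons within that endpoint × duration × timepoint family. Expected
cells below 5 produce a warning but the test is still computed; an all-zero
margin is a degenerate-table error.

Conventions: abnormality endpoints are analyzed on final-timepoint
(120 hpf) cumulative data except "unhatched", scored at 72 hpf (hatching
normally completes by ~48–72 hpf); both are configurable. Abnormality
denominators are survivors at the screening timepoint; mortality uses all
embryos. "Total abnormalities" counts larvae with ≥ 1 morphological
abnormality, not the sum of endpoint counts. Conditions reaching 100%
cumulative mortality by the final timepoint are gated out of abnormality
and behavior analyses (the gate fires at exactly 100%, not near-total
mortality).

## DEG filter and accounting

A gene is significant in a condition when |log2FC| ≥ 0.75 (inclusive) and
adjusted p < 0.1 (strict); missing adjusted p (NA from upstream independent
filtering) is never significant and is tallied as "untested". Two
duration-total policies are provided because published tables mix them:
`"sum"` adds per-concentration counts (a gene hit at two concentrations
counts twice); `"unique"` counts distinct genes, reporting genes with
opposite signs at different concentrations as *variably regulated*. Venn
overlaps are exact region decompositions for up to 5 named sets; combined
per-chemical sets union a chemical's significant genes over all
concentrations and durations before intersecting. Gene identity is exact
string match on `gene_id`; alias/ortholog resolution is out of scope.
Functional-category annotation is a plain left-join against a user-supplied
gene→category map (unmapped genes become "unassigned"); no pathway
enrichment statistic is computed.

## Unit conversion

µg/L = nM × molar mass (g/mol) × 10⁻³. Molar masses are computed from
molecular formulas with 2020 IUPAC conventional atomic weights and stored
as validated constants: triclosan C12H7Cl3O2 = 289.54 g/mol, triclocarban
C13H9Cl3N2O = 315.58 g/mol, 4-nonylphenol C15H24O = 220.36 g/mol. The
registry is user-extensible via TSV. Display rounding is 1 decimal; full
precision is retained internally and round-trips to machine precision.

## Synthetic data: what it emulates, and what it does not

* **Traces** — per-bin distances are truncated normal (clipped at 0) with
  phase-specific means: dark baseline 1.2 cm/bin, light 0.4 cm/bin
  (light:dark ratio ≈ 0.33, the normal pattern), CV 25%, 24 larvae/group.
  Group effects scale the phase means multiplicatively. Planted bin
  outliers multiply a bin by `outlier_scale` (default 6). Planted
  non-responders get light mean = 1.2 × their dark mean: comfortably above
  the 0.9 ratio cutoff so that, even with bin-level noise in the *measured*
  ratio (SD ≈ 0.04 at 120 bins/phase-type), the ratio rule removes them
  deterministically. Bins are independent given phase — real traces have
  within-larva temporal autocorrelation and between-larva variance
  heterogeneity that the generator does not model, so passing tests
  demonstrate algorithmic correctness and calibration under the stated
  model, not robustness to those features.
* **Screening** — static per-larva Bernoulli abnormality states with
  `logit(p) = logit(baseline) + log(OR)`, a constant per-24-h death hazard,
  150 embryos per condition. Hatching dynamics are not modeled
  ("unhatched" is a static binary). Counts are reported per timepoint with
  the survivor-denominator convention above.
* **DE tables** — null genes: log2FC ~ N(0, 0.2), raw p ~ U(0,1); planted
  genes: |log2FC| ~ N(1.5, 0.3) (optionally truncated below), random sign,
  raw p ~ U(0, 1e-5). Adjusted p is Benjamini–Hochberg within condition
  (the standard default of upstream DE tools whose outputs these tables
  emulate; no negative-binomial read-count model is simulated). Genes
  shared across chemical sets are planted in the first condition of each
  member chemical and nowhere else, which suffices for combined-set overlap
  recovery.

Determinism: every generator draws from `default_rng([seed, salt])` with a
fixed per-generator salt, so identical configs are bit-identical and adding
one generator never perturbs the others.

## Problem sizes used in tests and the acceptance script

Property suites use 500 random 20-bin cohorts (QC invariants vs a
brute-force pair enumeration), 1000 random small tables (chi-square vs the
Σ(O−E)²/E oracle), and 200–300 random set families (Venn vs a
membership-vector oracle). Calibration runs use 1000 null ANOVA replicates
(4 groups × 24), 200 replicate trace simulations for hypoactivity detection
and non-responder exclusion, and 5000-gene tables for planted-overlap
recovery — sizes chosen to give stable Monte-Carlo estimates while keeping
the suite quick to run end to end.

## Known limitations

* Per-trace (not pooled) QC reference populations are a documented choice;
  results under a pooled convention could differ for cohorts with strong
  between-larva scale differences.
* The chi-square pairwise family is defined per endpoint × duration ×
  timepoint; a stricter family definition (e.g., across endpoints) would
  give larger corrections.
* The DEG generator draws effect size and p-value independently, so joint
  threshold passes are rarer than in real DE output where the two are
  correlated.
* No dose–response modeling, trend tests, mixed-effects or time-resolved
  behavioral analysis; these are outside the pipeline's scope.
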