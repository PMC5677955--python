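# Methods

## The model

A mosaic variant is a somatic change confined to a clone occupying a
fraction *f* of blood cells; a heterozygous variant on that clone is
expected at allele fraction *f*/2 < 0.5 among informative reads.
`mosaicburden` treats the read count at a called non-reference genotype as
Binomial(d, q): d = ref + alt reads from the AD field, q = 0.5 under the
germline-heterozygote null. The mosaic call is the one-sided lower-tail
exact test P(X ≤ alt), thresholded at α = 0.001, combined with a strict
depth gate d > 20 (21 informative reads minimum). Two deliberate choices:

* **One-sided lower tail.** The scientific claim is directional (allele
  balance *below* 0.5); a two-sided option exists (`CallerParams.two_sided`)
  but is off by default.
* **AD sum, not DP.** DP may include uninformative (filtered, overlapping)
  reads; depth is defined as the sum of allelic depths. DP is logged for
  comparison when it disagrees.
* **No multiple-testing correction across sites.** The α = 0.001 cutoff is
  a fixed operating point of the classifier, not an inference; carrier
  status downstream is where inference happens.

Carrier status is per sample: at least one mosaic PTV call in the four
candidate genes (PPM1D, TET2, ASXL1, DNMT3A). PTV means stop-gain,
essential splice site (the donor/acceptor VEP classes, folded to one label
at read time) or frameshift.

## Association model

Logistic regression (binomial GLM, IRLS via statsmodels) of case status on
the carrier flag plus covariates, default {age, coverage}:

    logit P(case) = β0 + β1·carrier + β2·age + β3·coverage

OR = exp(β1), 95% Wald CI on the log-odds scale (the CI method is a
choice; a profile-likelihood CI can be obtained from the statsmodels fit
object if wanted). Age enters linearly in log-odds; coverage is the
per-sample mean depth over the candidate-gene target (per-sample rather
than per-cohort — the summary the metadata carries). Perfect separation is
detected (unbounded coefficient or exploding SE) and raised as an explicit
error recommending an exact or penalized fallback rather than reporting a
meaningless Wald summary. Degenerate-but-valid designs (no carriers in one
arm, constant covariate) return a `testable=False` result instead of
raising.

The 2×2 population-cohort summary reports stratum event rates as
percentages and the crude OR (a·d)/(b·c), with the Haldane–Anscombe 0.5
correction flagged when any cell is zero, and an optional age-adjusted
logistic p when per-sample data are available.

## Burden resampling

For phenotype P with N cases, candidate sets of N samples are drawn
uniformly without replacement from the pool of **all** cases (P's own
cases included — an exclude-self variant would change the null subtly and
is not what the procedure specifies). A set is accepted iff a two-sided
Wilcoxon rank-sum test of its ages against P's ages has p > 0.05 (the
acceptance threshold is configurable; "non-significant age difference" is
the criterion). The empirical p is the fraction of B = 10⁴ accepted sets
whose carrier frequency strictly exceeds P's (`strict_greater`); the
add-one estimate (exceedances+1)/(B+1) is always reported alongside, since
the literal fraction can be exactly 0 and is slightly anti-conservative
under ties. The scan tests every phenotype overall and per gene, with
Bonferroni threshold 0.05/n_phenotypes recomputed from the data (0.0025 at
the 20-phenotype reference design).

Implementation notes:

* Candidate sets are drawn in vectorised batches (random keys +
  `argpartition`); the rank-sum filter is evaluated with a vectorised
  z-test without tie correction that matches `scipy.stats.ranksums`
  exactly (tested), so the all-tied-ages edge gives p = 1, never NaN.
* When every age in pool and target is identical the filter accepts every
  draw and the carrier count of a uniform N-subset is *exactly*
  hypergeometric; counts are then sampled directly with
  `rng.hypergeometric`. This is the same sampling distribution, not an
  approximation, and makes large null-calibration studies cheap.
* If fewer than one candidate in `max_draw_factor` (default 50) is
  accepted, the phenotype is declared age-unmatchable with an explicit
  error naming it.
* Null calibration (tests and acceptance script) uses a pool of 4000
  cases, 5% carriers, a target phenotype of 1000 — sizes chosen so the
  hypergeometric null is fine-grained enough that the discrete false-flag
  rate sits near the nominal 0.0025.

## Tumor depletion

Paired Wilcoxon signed-rank, one-sided alternative blood_ab > tumor_ab,
zero differences dropped. For n ≤ 25 the exact null is computed by a
dynamic programme over the 2ⁿ sign assignments of the (doubled, so integer
under midrank ties) ranks; above that, the normal approximation with tie
and 0.5 continuity corrections. The pairing is per sample-site (signed
rank, not rank-sum) because blood and tumor are two measurements of the
same event. Both a pooled test and per-gene tests are provided. The
companion coverage comparison (two-sided signed-rank on depths, direction
reported) checks that depletion is not a sensitivity artifact; no
tumor-purity or contamination modeling is attempted — tumor allele balance
is used as-is, so a small residual fraction is expected rather than zero.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes,
at the level of called genotypes:

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 7979 / 6177 | reference cohort sizes |
| case/control age | N(60, 12) / N(50, 12), truncated at 18 y | ~10-year mean gap |
| case/control depth mean | 33× / 29× | mean target coverage per cohort |
| coverage_cv | 0.10 | per-sample Gamma spread of latent mean coverage |
| carrier_base_rate | 0.008 | carrier probability for a 60-year-old control |
| carrier_age_slope | 0.07 /year | log-odds increase (~doubling per decade) |
| carrier_case_log_or | log 1.26 | injected conditional case–carrier effect |
| gene_weights | DNMT3A .45, TET2 .25, ASXL1 .18, PPM1D .12 | clonal-hematopoiesis spectrum |
| mosaic_af_range | (0.10, 0.20) | clonal allele fraction, uniform |
| tumor_depletion_af | 0.02 | residual tumor allele fraction at mosaic sites |
| germline_site_rate | Poisson(1) per sample per gene | background het sites, AF 0.5 |

Carrier truth is drawn from the logit-linear model, each carrier gets
exactly one mosaic PTV (carrier status, not multiplicity, is analysed), and
site depths are Poisson around a per-sample latent mean (Gamma-distributed
around the cohort mean so the coverage covariate has within-cohort
variance; a negative-binomial per-site option adds overdispersion).
Alternative read counts are Binomial(depth, AF) truncated to ≥ 1 — a site
record exists only because a variant was called, and a simulated carrier is
defined as a sample whose clone is represented in the sequenced reads; this
keeps the carriers-equal-mosaic-sites conservation exact at the cost of a
slight upward truncation bias at very low AF·depth. Mosaic PTVs in PPM1D
and ASXL1 concentrate in the last exon and TET2 in exon 3 of its three-exon
blood transcript (concentration 0.9, configurable); DNMT3A is uniform.
Cases carry paired tumor reads at every site (tumor depth = blood depth
plus Poisson(4), so tumor coverage is never worse), mosaic sites at the
residual fraction, germline sites at 0.5. The uniform AF distribution is a
modeling choice — the variance of real clonal fractions is unknown.

What the generator does **not** emulate: read-level artifacts (mapping,
strand bias, contamination), indel representation differences between
callers, multi-allelic sites, relatedness and ancestry structure, clonal
dynamics over time, and per-phenotype carrier-rate differences (burden
power tests construct those cohorts directly). Passing tests therefore
demonstrate the statistical machinery is correct under the declared model,
not that real-data artifacts are handled.

## Verification design

* The binomial caller is checked against exact integer enumeration of the
  Binomial(d, ½) CDF for every (alt, depth) with depth ≤ 50 (≤ 1e-12).
* The resampling test is checked against exhaustive subset enumeration on
  pools ≤ 12 (including a closed-form 1/6 worked example) within 3
  Monte-Carlo standard errors at B = 10⁵.
* The exact signed-rank tail is checked against full 2ⁿ sign-flip
  enumeration for n ≤ 12, and the large-n path against scipy's corrected
  normal approximation.
* Null calibration: no-association cohorts of 5000 + 5000 samples (equal
  ages and depths) run end-to-end through simulation, calling and the GLM
  — the 95% CI covers OR = 1 at its nominal rate over 200 seeds; the
  burden false-flag rate at 0.0025 is checked over 2000 permutation nulls.
* Parameter recovery: 100 cohorts at the full reference design with the
  injected conditional carrier OR of 1.26, fitted age-adjusted on the
  generator's truth labels — the criterion isolates the estimator from
  caller sensitivity, which is characterised separately (≥ 90% of true
  carriers recovered at 60× with AF 0.10–0.20; at 29–33× sensitivity is
  genuinely partial and slightly depth-dependent, which is why the
  coverage covariate exists). The acceptance script also reports the
  median called-carrier OR from the full read-level path for comparison.

Problem sizes in the test suite (cohorts of a few hundred to 10⁴ samples,
10²–10³ calibration replicates, B up to 10⁵) were chosen as the smallest
designs that make each statistical check sharp.

## Known limitations

* Wald CIs undercover slightly when carriers are very few (< ~20); the
  separation guard catches the extreme case but small-sample inference
  would need exact or Firth methods, which are out of scope.
* The literal-fraction empirical p can be 0; use the add-one value for
  downstream meta-analysis.
* The age-match acceptance filter conditions on non-significance, which is
  not the same as matching the full age distribution; with strongly
  disjoint age strata the procedure correctly refuses rather than
  silently mismatching.
* Frameshift allele depths are consumed as given in AD; no indel
  re-normalisation is attempted.
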