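# Methods

## Model and assumptions

The analysis targets F₂ seeds self-pollinated on a single F₁ plant
heterozygous (*Dd*) at a biallelic dormancy locus. Three assumptions carry
everything:

1. **Tissue genotypes are coupled through the gametes.** Egg and polar
   nuclei are genetically identical, so the triploid endosperm dose
   (male + 2·female D count) determines the embryo genotype and the ordered
   gamete pair uniquely. All estimators work on endosperm doses 0–3;
   embryo-level quantities are derived, never separately observed.
2. **Maternal tissue is constant.** Every seed's testa/pericarp is *Dd*, so
   maternal action produces no between-seed genetic signal; it is inferred
   from the *absence* of offspring-tissue signatures, and a locus acting in
   both maternal and offspring tissues is reported as "offspring at least".
3. **Selection acts only through the germination endpoint.** Partial
   after-ripening plus a fixed incubation window split seeds into germinated
   and nongerminated subpopulations; there is no viability selection.

Two alleles only; multi-allelic loci, linkage between the two loci of a
digenic design, and joint maternal–offspring likelihood models are out of
scope.

## Frequency estimators and tests

Genotype counts → genotypic frequencies → overall allelic (F_d) and
male/female gametic (F_d′, F_d″) frequencies, with F_d ≡ (F_d′ + F_d″)/2.
The χ² test uses the Mendelian 1:1:1:1 expectation with df 3; expected
counts below 5 produce a warning but never block computation (the reference
analyses run χ² at N = 43). Tests of a frequency against 0.5, and of
F_d′ = F_d″, use the normal approximation with SE = √(2·F_d·F_D/N). This SE
is kept verbatim from the method being implemented even though it matches
neither the binomial SE at N trials nor at 2N trials; exact binomial
alternatives (N trials for a gamete frequency, 2N for the overall allelic
frequency) are available behind `method="exact"` and reports label the
method used. All tests are two-sided; no multiplicity correction is applied
across loci or experiments, matching the source analysis. Significance is
tiered at 0.05/0.01/0.001 in rendered tables.

`counts_from_frequencies` inverts printed three-decimal frequency summaries
to integer counts: largest-remainder apportionment of freq·N, then a bounded
±2 local search keeping the composition whose implied frequencies fall
within one printed unit (tolerance 1.05×10⁻³) of all four values with the
smallest maximum deviation. The one-ulp tolerance is deliberate: published
summaries are sometimes truncated rather than rounded. Exact inversion is
identifiable only while 1/N exceeds the printed resolution (N < 1000);
above that the reconstruction is only guaranteed to re-round to the printed
values.

## Germination curves

The population curve divides cumulative germinated counts by the number of
seeds placed in the test. Per-genotype curves use the day-independent class
total T_i = (class-i seeds germinated over the whole test) + N_ng·F_ng,i,
with N_ng counting every nongerminated seed (missing genotypes included) and
F_ng,i estimated from the genotyped nongerminated seeds. A variant that
re-enters the day-dependent cumulative count into the denominator is kept
behind `literal_denominator=True` for comparison only: it inflates early
percentages and forces every curve toward its own ceiling, which contradicts
the observed plateaus below 100 % for dormant genotype classes. Allele
trajectories are cumulative-to-date (seeds germinated by day j), not
per-interval; the counting grid supports half-day or daily counts starting
at day 2.

## Effect models

Response = the counting-grid day at which germination was scored, i.e. an
interval-censored time collapsed to the right endpoint of its interval.
Embryo coding x = dose−1, z = ±½; endosperm coding x = dose−1.5, z₁ = [DDd],
z₂ = [Ddd]. Stepwise selection uses forward entry and backward stay both at
0.05 — the implemented procedure fixes the significance level at 5 % for
both thresholds rather than adopting a looser conventional entry/stay split
— and the intercept is always retained. Fits are ordinary least squares
(statsmodels); the two-locus screen is a two-factor factorial ANOVA on
embryo genotypes with sequential (Type I) sums of squares in the documented
order (A, B, A×B), since unbalanced subpopulations make SS-type choices
matter.

A practical caveat the simulator makes visible: when germination is limited
by the end of the window (strong endpoint selection), within-subpopulation
timing contrasts are compressed — most of the genotype effect is spent on
who germinates at all, not when — so effect estimates from heavily selected
subpopulations are conservative and may fail the 5 % screen at modest N.
Parameter-recovery validation therefore uses designs whose germinable
component lies inside the window (below).

## Tissue classification

Rule 1 (offspring): χ² rejects in the germinated subpopulation and
F_d(G) > F_d(NG) when a nongerminated side exists. Rule 2 (maternal): no χ²
or F_d-vs-0.5 test rejects in any examined sample. Rule 3 (SDL): χ² rejects
in a joined population or random sample, where germination selection cannot
act; the gamete side is whichever of F_d′/F_d″ rejects 0.5. Preferential
fertilization is flagged only from a joined/random sample with the male
frequency deviating and exceeding the female one. The endosperm/embryo
refinement requires agreement of two independent signatures: (i) a seeded
permutation test (default 10,000 relabellings; the difference in mean
censored germination day between the Ddd and DDd classes, nongerminated
seeds placed at end_day + 1) — these classes share the *Dd* embryo, so only
endosperm dose can separate them; and (ii) the germinated-sample gamete
asymmetry F_d″ > F_d′ that a per-copy endosperm effect produces.
Disagreement returns "indeterminate" with both evidence lines. Any rule
whose inputs are missing is reported as not-evaluable, never silently
passed. α defaults to 0.05 everywhere and is configurable. There is no
formal equivalence test behind the maternal rule — absence of significance
is the criterion, as in the source method — so maternal calls at small N
are weak evidence.

## Simulator

Gametes are Bernoulli draws with per-side d-transmission probabilities
(0.5 = Mendelian; 0.57 on the male side reproduces the observed
preferential-fertilization distortion). Latent germination time is Gaussian
(default) around baseline + the coded genetic shift of the configured
tissue; a lognormal option exists for skewed-germination realism. The
Gaussian default keeps the OLS effect models well-specified so recovery
tests isolate estimator behavior. Incomplete after-ripening is modelled as
a genotype-independent mixture: a seed stays deeply dormant with probability
`dormant_fraction` (shifted by `dormant_shift_days`, default 30 d, beyond
any window). This reflects the observed germination heterogeneity of
pure-line samples, which is nongenetic; a uniform shift applied to all seeds
could only produce partial germination through endpoint truncation of every
seed, which both distorts recovered effects and contradicts pure-line
heterogeneity. Censoring happens only at `end_day`; observed days are
rounded up to the counting grid (day 2 start, half-day or daily counts).
Genotyping dropout is independent of genotype; a separate nongerminated-seed
success rate models the harder DNA recovery from ungerminated endosperms.
Two loci assort independently.

What the generator does **not** emulate: linkage, pollen-competition
mechanisms behind transmission distortion, seed-to-seed microenvironment
correlation within dishes, after-ripening kinetics, or contamination.
Passing tests therefore validate the estimators and decision rules under
the stated sampling model, not robustness to those real-data features.

Preset designs (`scenario_presets`) mirror the three reference systems and
the digenic experiment at their real scales (631–1529 seeds, 20–77 %
germination): a maternal-mode design, an endosperm-additive design (0.47 d),
an embryo-additive design (0.53 d) with male-side transmission 0.57 and 50 %
nongerminated genotyping success, and a two-locus maternal+embryo design
(0.73 d). The selection-driven presets place the germinable component near
the end of the 7-day window so that genotype-dependent censoring produces
the published distortion patterns.

## Validation designs and problem sizes

* Published-summary reproduction: all 18 usable frequency rows, exactly
  (three misprinted entries in the source table are annotated in
  `endodorm.datasets` and excluded).
* Oracle agreement: χ² vs a brute-force Σ(O−E)²/E on 1000 random count
  vectors (10⁻⁹); OLS vs normal equations on 50 random designs (10⁻⁸).
* Parameter recovery: N = 600 seeds, additive 0.5 d (also 0.22–0.73 d),
  noise SD 1 d, ~30 % germination via a 0.68 dormant fraction with the
  germinable component centred at 5 d in a 10-day half-day-count window;
  500 replicates for unbiasedness and 95 % CI coverage (stepwise selection
  keeps the additive term in ≈99 % of replicates at 0.5 d; the small-effect
  runs use full-model fits to avoid selection censoring of the recovered
  distribution).
* Classifier calibration: 800 maternal-mode replicates judged on
  germinated-seed evidence, where the offspring rule is exactly the χ² test
  and must fire at α. Power: 200 replicates per preset (>80 % correct calls),
  with 2,000 permutations per replicate — p-values only need resolution near
  α, and 2,000 relabellings put the Monte-Carlo SE of a p near 0.05 at about
  0.005. SDL detection at N = 484 random seeds is compared against the
  noncentral-χ² power for that design rather than asserted as a constant.
* Curve properties: one 20,000-seed endosperm-additive population for the
  plateau identity and dose ordering at every counting day.

## Known limitations

* Maternal calls rest on accepting null hypotheses; report them with the
  sample sizes that back them.
* Effect estimates from strongly selected subpopulations are biased toward
  zero (endpoint compression); the package estimates them faithfully but
  they should be read as conditional-on-germination effects.
* The published SE formula √(2F_dF_D/N) is nonstandard; star annotations
  computed with it can disagree with exact binomial tests near thresholds.
* Reconstruction of counts from printed frequencies is non-identifiable for
  N ≥ 1000 (one printed ulp < 1/N); derived allelic frequencies remain
  correct to printed precision.
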