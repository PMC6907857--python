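# Methods

## The liability-threshold model of penetrance

Incomplete penetrance — a deleterious genotype producing its phenotype in
only a fraction of carriers — is modelled as a threshold character.  Each
animal carries an unobserved liability, normally distributed in a
population, and shows the (binary) phenotype when liability exceeds a
phenotype-specific threshold.  For a population with incidence *p* the
distance from the mean liability to the threshold is the probit

    x = Φ⁻¹(1 − p)    (SD units of liability)

`incidence_to_liability` implements this with an absolute tolerance of
1e−9 against `liability_to_incidence` on the round trip.  An incidence of
exactly 0 or 1 has an infinite probit; it is replaced by ±`cap`
(default 4.0 SD — chosen because a trait that is fully penetrant in a
scored sample of realistic size is indistinguishable from a distance of
about 4 SD) and flagged `capped`.  Capped values are bounds, not
estimates: `strain_liability_difference` refuses them without an explicit
override, and the multiple-threshold fit excludes them by default and
reports the exclusions.  An optional (k + 0.5)/(n + 1) continuity
correction is available but off by default.

Because different phenotypes of the same mutant share one liability
distribution with different thresholds (the multiple-threshold model), the
observed x for strain s and phenotype k decomposes as x = T_k − μ_s.
`fit_multiple_threshold` estimates the strain means μ and thresholds T by
ordinary least squares with one anchor strain's mean fixed at 0 — only
differences are identifiable, and all reported quantities are differences.
The fit demands a connected strain-by-phenotype design graph after capped
cells are removed; a disconnected design raises an identifiability error
naming the components rather than returning arbitrary offsets.

## Penetrance statistics

Penetrance estimates are k/n over *scored* animals only: an unscored
(NA) phenotype never enters numerator or denominator.  Intervals are exact
Clopper–Pearson by default (configurable).  Two-group comparisons use the
two-sided Fisher's exact test under the probability-mass rule (all tables
with the observed margins whose hypergeometric probability is at most the
observed one, with 1e−7 relative tolerance — the convention of the common
reference implementations).  Sidedness of the original analyses is not
documented anywhere authoritative, so two-sided was chosen as the
conservative default; on the 8/44 vs 18/44 overexpression counts it gives
p = 0.034, significant at α = 0.05 (a one-sided reading gives ≈ 0.02).
A table with an all-zero margin is uninformative, not invalid: it returns
p = 1 with a warning.  Families of tests (all phenotypes within one
comparison) are adjusted by Benjamini–Hochberg FDR or the Hochberg step-up
rule; the family definition is configurable because the original grouping
of tests into families is not documented.

## Comparative-Ct quantification

Technical replicates are averaged per (sample, gene) before
ΔCt = Ct_target − Ct_reference; the biological unit is the (pooled) sample.
ΔΔCt is the difference of group-mean ΔCt between comparison and calibrator
groups and the fold change is 2^−ΔΔCt.  Group tests run on ΔCt — the log
scale — for variance stabilisation, with pooled-variance t-tests by default
(Welch optional) and Tukey HSD across the declared group family.  Standard
curves are OLS of mean Ct on log10 quantity; primer acceptance is
|slope − (−3.3)| ≤ 0.3 and efficiency 10^(−1/slope) − 1 is reported for QC
but never used to correct folds (the plain comparative-Ct method assumes
near-perfect doubling and is gated on curve acceptance instead).  The curve
fitter requires ≥ 3 distinct positive quantities and warns (rather than
errors) below a one-decade span, since classic doubling series such as
8:4:2:1 span slightly less than a decade.  "Undetermined" Ct cells are
rejected unless the configuration maps them to an explicit ceiling.

## The breeding simulator

The simulator is the package's synthetic-data generator and defines the
study conditions for every stochastic test.

**Architecture.** Liability = polygenic value + environment.  40 unlinked
diallelic loci with equal, exchangeable effects at founder frequency 0.5;
the per-allele effect is set so founder additive variance equals h² = 0.6,
and σ_E = √(1 − h²), giving total founder SD 1.  Loci assort independently
(free recombination); each parent transmits one allele per locus.

**Focal locus.** Founders are heterozygous carriers.  Offspring segregate
1:2:1.  Genotype adds a liability offset: δ_wt = 0, δ_het = 0.5,
δ_mut = 3.0.  The offsets were fixed a priori so that (i) founder
heterozygote penetrance of the selection phenotype is effectively zero
(≈ 0.2%, a recessive allele) and (ii) a high-direction mean shift of
1.5–2 SD brings heterozygotes within reach of the threshold, reproducing
the recessive → partial-dominant conversion, while the low line never
shows heterozygote phenotypes.

**Thresholds.** Phenotype thresholds are expressed relative to the founder
mutant mean and parameterised by founder mutant incidences.  The selection
phenotype (ectopic bone) is anchored at incidence 0.32, i.e. threshold
distance Φ⁻¹(0.68) = 0.468 SD.  The other five phenotypes' founder
incidences (0.55–0.9999) are documented inventions spanning the observed
spread from partially to fully penetrant; the near-1 value for the
short-symplectic phenotype keeps it fully penetrant in both lines.

**Lethality.** A single extra threshold on total liability gates survival
to adulthood, at −0.5 relative to the founder mutant mean (absolute 2.5).
Chosen a priori so that heterozygotes remain overwhelmingly viable
throughout the program (both real lines were maintainable for 7–8
generations) while most founder mutants fail to reach adulthood (~31%
viability) — under low-direction selection mutant viability rises to
~88% (lethal → viable conversion), and under high-direction selection
mutants become fully inviable as adults.  Whether lethality shares the
phenotype liability or is an independent process is unknown; the shared
single threshold is the simplest mechanism that produces the conversion.

**Program.** Per generation: form 8 het×het pairs (full sibs after
generation 0), 60 offspring each; score every homozygous-mutant offspring
(at the larval stage, i.e. before lethality acts) for each phenotype;
select the pair with the extreme mutant penetrance of the scoring phenotype
(ties to the smallest family index; a random-tie option exists); continue
from its surviving heterozygous offspring.  Generation numbering follows
the pedigree convention: generation 0 is the founding (unselected) pairs'
offspring, so generation g has experienced g selection rounds.  Family
counts and clutch size are documented defaults (the real program's are not
published); selection by progeny testing on observed penetrance — not
truncation on liability — mirrors the actual protocol, and inbreeding
depression of additive variance is emergent, not imposed.

**What the generator does and does not emulate.** It reproduces Mendelian
segregation, family structure, selection on a noisy binomial penetrance
estimate, inbreeding, and threshold-character geometry.  It does not model
linkage, unequal or non-additive modifier effects, genotyping error,
observer disagreement, clutch-size variation, or shared-tank environmental
correlation; passing tests therefore validate the statistical machinery
under the stated generative model, not those aspects of real scoring data.

## Numerical and reporting choices

Probit transforms use scipy's inverse survival function; threshold fits use
`numpy.linalg.lstsq` on the design matrix (exactly-determined consistent
systems recover parameters to machine precision).  Liability values are
reported to three decimals and strain separations additionally at one
decimal.  Full precision is kept internally and in machine-readable
outputs; rounding happens only at the reporting layer.  Pipeline run
directories are never overwritten; every stochastic stage records its seed
in the run summary and manifest.

## Problem sizes

The replication experiment and the acceptance computation use 50 replicates
per direction of the default program (8 pairs × 60 offspring × 8
generations), the package's standard experiment size; it gives a binomial
Monte-Carlo error on median penetrance well under one percentage point at
both endpoints.  The exhaustive Fisher validation covers all 46,375 tables
with total n ≤ 30; the qPCR type-I-error simulation uses 1,000 null
repeats of a 2 × 6-sample design.

## Known limitations

- Heritability, locus count and founder incidences for non-selected
  phenotypes are assumptions; only the selection phenotype's founder
  incidence is anchored by a reported threshold distance.
- The liability scale after strong selection is compressed by the loss of
  additive variance, so probit distances computed from late-generation
  incidences are in units of the *current* (smaller) liability SD — the
  same caveat applies to the published strain-separation arithmetic.
- Fisher sidedness and the original multiplicity family are undocumented;
  both are configurable and the defaults are stated above.
- The outcross ("half-low") arm of the original pedigree draws the
  unselected parent from the founder distribution if simulated; allele
  frequencies of real unselected stocks may differ.
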