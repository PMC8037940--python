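# Methods

This note records the statistical models, default parameters and design
choices behind `fluoropanel`, in enough detail to judge what the package's
tests do and do not establish.

## Variant catalogue

A catalogue holds 22 candidate variants and 15 panel models. Per-allele
activity values are a total function of the CPIC-style function class
(no function → 0.0, decreased function → 0.5, common toxicity-risk → 1.0);
a file may state `allele_activity` explicitly but an inconsistent value is
a validation error — the class, not the number, is the source of truth.
Variants are keyed by rsID where one is established and by an HGVS-style
short name otherwise. Entries flagged `provenance: curated` (everything
except the four CPIC alleles) carry activity values, allele frequencies
and hg19-style coordinates assigned from published function classes and
public frequency data; they are sensible, editable defaults rather than
authoritative annotations, and the genomic coordinates exist mainly so the
simulator can emit well-formed VCF. The two-allele sets behind each model
follow the published panel definitions, including the one panel (model 15)
that uses a positivity cut-point of 2 rather than 1.

## Genotype handling

Dosage is the count of the catalogue risk allele per genotype (0/1/2,
missing for `./.` and half-calls). VCF records are matched by rsID first,
then by chrom:pos:ref:alt; multiallelic records overlapping a catalogue
variant are rejected rather than guessed at. Panel testing uses only
samples genotyped for every variant under test (per-comparison complete
cases, using the union of both panels' variants), so different comparisons
can legitimately have different n.

Imputed genotype probabilities are out of scope: dosages are hard calls,
which reproduces the convention of hard-coding imputed genotypes above a
posterior threshold and marking the rest missing.

## Exact Hardy–Weinberg test

Conditional on the observed allele counts, the heterozygote count follows

P(H = h) = N! n_a! n_A! 2^h / (n_AA! h! n_aa! (2N)!),

and the two-sided p-value sums P over all h no more probable than the
observed one (probability ordering). The implementation evaluates terms
with log-gamma and normalises; a relative tolerance of 1e-9 on the
"no more probable" comparison keeps symmetric, exactly-tied terms
together under floating point. An exact-rational enumeration oracle
(Fractions over math.comb weights) in the test suite agrees to 1e-12 for
N ≤ 500. A chi-square test was deliberately not used: most catalogue
alleles have 0–2 carriers per 888 patients, far outside its validity.
QC (call rate < 0.97, HWE p < 0.05, monomorphic) flags but never excludes:
a rare-variant HWE departure can be a confirmed genotype cluster, so
exclusion is left to the pipeline caller.

## Activity score and tiers

The activity score sums exactly two alleles: all deficiency-allele copies
are pooled (dosage-weighted), sorted by activity with catalogue order
breaking ties, the two least-active kept, and normal alleles (1.0) pad the
remainder. Phase is unknown, so two deficiency alleles in one patient are
assumed in *trans* (the conservative reading) and every such compound
genotype carries a warning; more than two copies also warns and still sums
two. A homozygous decreased-function genotype scores 1.0 and tiers as high
risk. Missing genotypes at deficiency variants contribute no copies —
classification degrades gracefully rather than failing, since tier output
is advisory and accompanied by the rationale string naming the observed
alleles. The tier function is total over (activity score, HFS carriage)
and the suite tests all ten reachable combinations.

## Binary codings and diagnostic metrics

Grade ≥ 3 ("012 v 34"), grade 4 ("0123 v 4") and the mucositis/stomatitis
coding "012 v 3" are supported; the last is implemented as grade ≥ 3 — on
the 0–3 grade range the name implies, this is identical to "= 3", and a
stray grade-4 event should count as test-positive rather than silently
negative. Haematological toxicity is the per-patient maximum of
neutropenia and thrombocytopenia; global toxicity the maximum over the six
contributing endpoints, defined only for patients with at least one of
them recorded (a missing endpoint excludes the patient from that
endpoint's analysis; it is not imputed as grade 0). Proportion CIs are
Wilson score intervals (statsmodels); likelihood-ratio CIs use the
standard log method with SE
sqrt(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)) for LR+ (and the analogous
form for LR−). The source analysis reports point estimates only, so the
CI methods are this package's choice of standard practice.

## ROC analysis

Integer allele-count scores are heavily tied, so everything uses the
half-credit Mann–Whitney convention; the empirical curve has one threshold
per distinct observed score and its trapezoidal area equals the
rank-statistic AUC exactly (property-tested). Single-AUC CIs use the
DeLong structural-component variance.

The paired comparison resamples whole patients (both scores jointly),
unstratified by outcome; a resample that loses an outcome class is redrawn
and counted. "Normal model" intervals — ΔAUC ± z·SE with SE the SD of the
bootstrap differences — are primary, with raw percentile intervals
reported alongside; the Wald p-value is the two-sided normal tail of
ΔAUC/SE, with the SE = 0 degeneracy (identical scores) mapped to p = 1.
Stratified case/control resampling is available as an option for very rare
outcomes. One seeded generator drives each comparison and the seed is part
of the result object.

Calibration, measured: under the null (two independent uninformative
scores, n = 888, prevalence 0.1, n_boot = 200) the rejection rate at
nominal 0.05 is ≈ 0.06 — mildly anticonservative, and a property of the
Wald ΔAUC statistic itself rather than of the bootstrap SE, since the
analytic DeLong test rejects at the same rate on identical data. The
calibration test uses 2000 Monte Carlo replicates because the ≈ 1% noise
of a few hundred replicates is comparable to the distance between the
true level and the acceptance bound.

Power uses the Hanley–McNeil variance
V(A) = [A(1−A) + (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]/(n₁n₀), Q₁ = A/(2−A),
Q₂ = 2A²/(1+A), under both hypotheses, two-sided by default; the inverse
query (minimum detectable AUC at target power) solves the power equation
by Brent's method. With 4 cases against 884 controls this gives power
0.55 at AUC 0.8, 0.87 at 0.9 and ≈ 1 at 0.99 — so "> 80% power across
AUC 0.8–0.99" holds only for AUC ≳ 0.87 at this event count; the claim is
accurate for less-rare codings (a few dozen events), where power is ≈ 1
throughout. For a common outcome (~25% prevalence) the minimum detectable
AUC at 80% power is ≈ 0.56.

## Synthetic cohorts

The generator emulates the structure of an 888-patient adjuvant
capecitabine trial, not any real dataset:

* **Genotypes** — independent per variant, HWE proportions at the
  catalogue's European frequencies: common SNPs at MAF 0.07–0.43, the two
  detected rare deficiency alleles at 0.0011 and 0.0006 (expected 1–2
  carriers per 888), undetected deficiency alleles at 0.0002 (expected
  0–1 carriers). No linkage disequilibrium by default.
* **Toxicity** — per endpoint, P(grade ≥ 3) = expit(logit(p₀) + Σ g·lnOR),
  log-additive per allele. Default baselines p₀: diarrhoea 0.07, vomiting
  0.03, HFS 0.23, neutropenia 0.02, thrombocytopenia 0.008,
  mucositis/stomatitis 0.018. Grade-4 fractions among events (diarrhoea
  0.14, neutropenia 0.17, vomiting 0.05, thrombocytopenia 0.10, HFS and
  mucositis 0) are calibrated so an effect-free 888-patient cohort yields
  on the order of ten grade-4 diarrhoeas, a handful of grade-4
  neutropenias and ~2 toxicity deaths — the reported rare-event counts.
  Death is sampled only among patients with a grade-4 event
  (baseline 0.13, shifted by no-function dosage). Grades 0–2 fill
  non-events at fixed proportions 0.60/0.25/0.15. Default odds ratios:
  4.4 per no-function allele and 1.59 per decreased-function allele on
  the five DPD-driven endpoints (the reported hazard ratio used as an OR,
  a reasonable approximation at these prevalences), 3.8 for rs12132152
  and 2.0 for rs2612091 on HFS, 1.5–1.6 for rs12022243/rs895819 on their
  endpoints. Endpoints are conditionally independent given genotype.
* **Planted strata** — deterministic genotype templates guarantee each
  sample's tier (e.g. the two critical-risk patients are one rs1801266
  homozygote and one rs3918290 × HapB3 compound heterozygote, mirroring
  the two canonical cases); default counts 2/52/236/598. Round-tripping
  through the classifier recovers the planted tier for 100% of samples.

What passing tests on this generator do **not** show: real cohorts have
LD between *DPYD* markers, correlated endpoints within patients,
imputation uncertainty, differential missingness and ethnically
structured frequencies — none of which are emulated by default (a
correlation knob exists but is off). Agreement between panel metrics here
and published values is structural (the arithmetic and the rank
statistics), not a re-estimate of the published effect sizes.

Same seed ⇒ byte-identical cohort; every cohort records its config and
seed.

## Pipeline and interfaces

`run_analysis` produces QC, per-model diagnostics, pairwise ROC
comparisons, the tier table with counts, a high-risk outcome summary and
a manifest (seed, version, config hash); every reported number is
re-derivable from the emitted tables. Outputs are delimited text and
JSON only. The CLI is a thin wrapper over these calls. Problem sizes in
the shipped tests and the acceptance script (cohorts of 250–888, 50,000
for parameter recovery, 200–1000 bootstrap iterations, 300–2000 Monte
Carlo replicates) were chosen to make every check precise enough to be
meaningful while keeping a full run in the order of a minute or two.

## Known limitations

* Phase-unaware activity scoring over-calls compound heterozygotes in
  *cis* (flagged, not resolved).
* The HGVS names are metadata; no syntax validation is performed.
* The bundled catalogue's curated frequencies/coordinates are defaults
  for simulation, not annotations for clinical use.
* The Wald ΔAUC test is mildly anticonservative (~6% at nominal 5%) for
  heavily tied scores with moderate case counts; for confirmatory use
  prefer the percentile CI or larger n_boot.
* Dose calculation, combination-regimen guidance and time-to-event
  analyses of dose modifications are out of scope; the tier report emits
  counts and recommendation text only.
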