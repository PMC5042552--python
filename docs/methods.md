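# Methods

## Score definition

At one biallelic-or-multiallelic protein site, donor and recipient each
carry an unordered pair of amino-acid alleles (phasing is irrelevant to the
definition and is ignored). The site contribution counts donor amino acids
absent from the recipient's genotype at that site. Two countings are
implemented:

- **distinct** (default): the number of *distinct* donor residues not in
  the recipient genotype. Recipient {A,A} vs donor {F,F} contributes 1.
- **allele-copy**: the number of donor allele *copies* whose residue is
  not in the recipient genotype. The same case contributes 2.

The two semantics agree except for a donor homozygous for a novel residue,
and allele-copy dominates distinct everywhere; both lie in {0,1,2}. The
default follows the description of contributions as "the number of
different amino acids" the donor encodes at a position; the allele-copy
reading of the per-allele sum is retained behind a flag and every report
names the mode used. The reference residue is an ordinary allele: a donor
homozygous-reference at a site where the recipient is homozygous-alternate
contributes, because only the donor-vs-recipient direction matters, not
which allele is the genome-assembly reference.

The score is the sum of contributions over the site set **P**: missense
variant positions in genes that contain at least one transmembrane
segment. The transmembrane gene list is an *input* (a Biomart-style TSV);
the package does not predict membrane topology, and the filter is
gene-level, not residue-level (a residue-level filter would require
per-transcript topology tracks and is out of scope). Stop-gains and
in-frame indels are excluded by default but admissible through the
`consequences` configuration.

## Genotype handling

Genotypes are read from VCF v4.x with cyvcf2. Multiallelic records are
kept as single sites — all alleles of one position feed one per-site
contribution, never pseudo-sites — and allele indices follow the VCF
convention (0 = REF, k = k-th ALT). Quality filtering mirrors upstream
genotype-caller semantics: a call is retained only if every non-reference
allele has read support ≥ 3 and the call has ≥ 3 distinct read indices
(both thresholds configurable); failing calls are demoted to no-calls, not
dropped, so missingness stays visible. Calls without support metadata
cannot be assessed and pass with a tally. Filtering is per-allele;
whether the original caller applied its thresholds per allele or per site
is not documented, and per-allele is the conservative reading.

Annotations come from a side-car TSV or from VEP-style CSQ strings using
the field layout declared in the VCF header (`Amino_acids` +
`Protein_position` preferred, HGVSp `p.Ala100Phe` notation as fallback).
A site annotated on several transcripts is counted once: the canonical
transcript if flagged, else the most severe consequence, ties broken
lexicographically by transcript id — deterministic and immune to
double-counting one physical mismatch.

Sites observed in only one sample are governed by a policy:

- `require-both` (default): the site keeps its true call status and the
  scorer skips it. Conservative; avoids inflating the score from coverage
  asymmetry between capture kits with different footprints.
- `assume-hom-ref`: the missing side is completed as homozygous
  reference, reflecting that exome assays imply the reference allele at
  covered positions without a variant call.

Which behaviour the original analysis used is not documented; both are
implemented and the default is the conservative one.

## Kidney-function models

eGFR is computed from serum creatinine, when not supplied directly, by the
4-variable IDMS-traceable MDRD study equation
(175 · Scr^−1.154 · age^−0.203 · 0.742 if female · 1.212 if black;
mL/min/1.73 m²). A provided eGFR is never overwritten. Computing eGFR
requires the recipient's age, sex and race; the clinical schema therefore
accepts an optional `recipient_age` column that is mandatory only when
eGFR must be derived.

Cross-sectional association at a fixed month is ordinary least squares of
the outcome on the score, reported as slope, adjusted r² and the two-sided
slope p-value.

The longitudinal model is a linear mixed model with fixed effects for
donor age at transplant, the pair's score and months post-transplantation,
plus a random intercept per transplant pair; the extended model adds the
HLA-A/B/DR mismatch count (0–6) as a single integer covariate. Fits use
statsmodels `MixedLM`. Nested models are compared by the likelihood-ratio
test after maximum-likelihood fits (REML fits are rejected by contract):
χ² = 2·(ℓ_full − ℓ_reduced), df = the difference in fixed-effect count.
The LRT is invariant to affine rescaling of the score. Reported
single-model estimates default to ML with a REML flag available, since the
estimation method behind published interval tables of this kind is often
unstated; confidence intervals are Wald (estimate ± 1.96·SE), chosen for
determinism and ubiquity.

Impact reports multiply each coefficient and its CI endpoints by an
*effective range* — the span over which the predictor plausibly varies.
Defaults: 480 months, 60 years of donor age, 1,700 score units, 6 HLA
mismatches; ranges are report inputs, not estimates.

### Numerical choices and degenerate designs

- The mixed-model optimizer tries `lbfgs`, then `bfgs`, then `powell`;
  the profiled Hessian can be singular under `lbfgs` on small cohorts
  even when the optimum is fine. Non-convergence after all three raises a
  named error.
- A random-intercept variance estimated at ~0 is a warning, not an error;
  the fit is still returned.
- With a single observation per pair the likelihood is flat along the
  σ²_pair + σ²_resid ridge. The fit warns and returns the OLS solution
  (all variance attributed to the residual, random-intercept SD 0), which
  is the natural convention on that ridge.
- Comparing a model with itself short-circuits to χ² = 0, df = 0, p = 1
  rather than erroring, so sweep code can treat it uniformly.

## The cohort simulator

The generator emulates the statistical structure the analysis assumes:

- **Sites.** 13,000 biallelic missense sites (matching the order of
  magnitude of contributing exome sites in real paired-exome data) in
  synthetic transmembrane genes, 10 sites per gene. Minor allele
  frequencies follow Beta(0.2, 2) truncated to (0.0005, 0.5) — a
  rare-skewed spectrum whose median MAF is below 0.05, consistent with
  the observation that contributing polymorphisms are mostly rare.
  Optional decoy sites (synonymous, or missense outside transmembrane
  genes) exercise site selection end to end.
- **Genotypes.** Hardy-Weinberg at every site; sites are unlinked (no LD).
  Unrelated pairs are independent draws; related pairs are parent-child:
  the recipient inherits one allele from the donor at every site and
  draws the other from the population. Half the pairs are related by
  default, matching the living-related/living-unrelated composition of
  typical living-donor cohorts; relatedness roughly halves the expected
  score and is the main source of between-pair score variance. Sibling
  IBD mixtures are not modelled — one haplotype-sharing mechanism
  suffices to test the directional property.
- **Clinical model.** eGFR(pair, T) = intercept + β_age·age + β_AMS·AMS +
  β_T·T + β_HLA·HLA + b_pair + ε with b_pair ~ N(0, σ_pair²) and
  ε ~ N(0, σ_resid²). Fixed-effect defaults are the combined-cohort scale
  estimates the models should recover: β_AMS = −0.01307, β_age = −0.47,
  β_T = −0.24, β_HLA = −0.57. Donor ages are truncated-normal (45, 12) on
  18–75; HLA mismatches uniform on 0–6. The intercept (102) puts mean
  eGFR near 55 mL/min/1.73 m² at mean covariates, and σ_pair = 12,
  σ_resid = 8 mL/min/1.73 m² split the noise so that repeated
  measurements are strongly correlated within pair. These noise and level
  values are generator calibration choices, not estimates from data.
  Every pair is observed at 12, 24, 36 and 48 months; alternating pairs
  add a 60-month visit, so 53 pairs yield 239 observations — the
  combined-cohort problem size used throughout validation.
- **Determinism.** One `numpy.random.Generator` seeded from the params
  drives every draw in a fixed order; the same seed reproduces all
  outputs (VCFs, CSVs, truth JSON) byte-for-byte.

What the generator does **not** emulate: linkage disequilibrium, genotype
error and coverage dropout, population structure in allele frequencies,
HLA haplotype structure, informative visit schedules or dropout, and
non-linear eGFR trajectories. Passing the recovery and calibration tests
therefore shows that the scoring arithmetic and the estimation machinery
are correct under the stated model — not that the model is adequate for
any particular real cohort.

## Validation problem sizes

Parameter-recovery and coverage checks use 100 replicate cohorts of 53
pairs (239 observations) at the 13,000-site panel; null calibration of the
AMS likelihood-ratio test uses 200 such replicates with β_AMS = 0; the
relatedness-direction check uses one 200-pair cohort. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
(the mean fitted AMS coefficient has a per-replicate SE near 0.006, so the
100-replicate mean is accurate to ~5% of the true −0.01307).

## Known limitations

- Scoring assumes annotations resolve every carried allele to a residue;
  sites with unresolvable alleles are excluded (and tallied), not guessed.
- Multi-sample VCFs are read per named sample; joint-called project VCFs
  with thousands of samples will work but are not optimised.
- The MAF summary relies on an external site → frequency table; no
  population database is bundled.
- Wald intervals and the χ² reference for the LRT are asymptotic;
  at very small cohort sizes (≲10 pairs) both are approximate, which is
  why the null-calibration acceptance band is 2–10% rather than exactly 5%.
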