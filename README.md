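# allogenomics

Donor/recipient genomic histocompatibility beyond HLA, for kidney
transplantation. The package computes the **allogenomics mismatch score
(AMS)** — a burden-style tally of donor amino-acid alleles that are absent
from the recipient's genome at missense sites in transmembrane genes — and
relates the score to longitudinal post-transplant kidney function with
linear mixed models. It is aimed at transplant genomics researchers who
have exome genotypes (VCF) for living donor/recipient pairs and serial
eGFR or creatinine measurements for the recipients.

## The score

Each diploid genome carries two alleles per autosomal site. For a
recipient *r* and donor *d*, every scoreable protein position *p*
contributes

&delta;(G<sub>r,p</sub>, G<sub>d,p</sub>) = #{amino acids encoded by the
donor's genotype at *p* that do not occur in the recipient's genotype at *p*}
&isin; {0, 1, 2},

and the score is the sum over the site set *P* (missense variant positions
in genes with at least one transmembrane segment):

&Delta;(r, d) = &Sigma;<sub>p &isin; P</sub> &delta;(G<sub>r,p</sub>, G<sub>d,p</sub>).

Each counted allele encodes a protein epitope the graft may display that
the recipient's immune system could recognise as non-self; the score is
therefore directional (donor-novel alleles count, recipient-novel ones do
not). Two semantics for a donor homozygous for a novel residue are
exposed: `distinct` (default, contributes 1) and `allele-copy`
(contributes 2); see `docs/methods.md`.

Association with graft function uses the random-intercept mixed model

eGFR ~ donor age + AMS + T + (1 | pair),

where T is months post-transplantation, optionally extended with the
clinical HLA-A/B/DR mismatch count (0–6). The AMS effect is tested by a
likelihood-ratio test between maximum-likelihood fits with and without the
score, and coefficients are converted to expected eGFR impacts over each
predictor's effective range.

## Worked example

The package ships a cohort simulator, so the full pipeline runs without
any real exome. Generate 8 pairs (half parent-child, half unrelated) with
2,000 scoreable sites, score them, and fit the models:

```
ams simulate --seed 42 --n-pairs 8 --n-sites 2000 -o cohort
ams score --pairs cohort/manifest.csv --vcf-dir cohort \
    --tm-genes cohort/tm_genes.tsv --annotations cohort/annotation.tsv -o out
ams associate --scores out/scores.tsv --clinical cohort/clinical.csv \
    --include-hla -o out
```

`out/scores.tsv` (after the provenance header):

```
pair_id total  n_sites_considered  n_sites_contributing  mode
pair000 153    2000                153                   distinct
pair001 137    2000                137                   distinct
pair002 150    2000                150                   distinct
pair003 124    2000                124                   distinct
pair004 236    2000                236                   distinct
pair005 233    2000                233                   distinct
pair006 223    2000                223                   distinct
pair007 238    2000                238                   distinct
```

Pairs 000–003 are parent-child and score visibly lower (124–153) than the
unrelated pairs 004–007 (223–238): sharing one haplotype identical-by-
descent halves the expected number of donor-novel alleles. `ams associate`
prints the AMS effect and its likelihood-ratio test,

```
AMS effect: -0.0943889 (LRT chi2=1.1327, df=1, p=0.2872)
```

(8 pairs are far too few for significance), and writes
`out/impact_table.txt`, which scales each coefficient by its effective
range to an expected total impact on eGFR:

```
           Estimate   2.50%  97.50%  Effective Range   Impact  Impact 2.50%  Impact 97.50%
predictor
donor_age   -0.5584 -1.3263  0.2095             60.0 -33.5037      -79.5769        12.5695
ams         -0.0200 -0.1197  0.0796           1700.0 -34.0422     -203.4684       135.3839
months      -0.1718 -0.3488  0.0052            480.0 -82.4589     -167.4320         2.5142
hla         -5.5911 -8.1182 -3.0640              6.0 -33.5465      -48.7091       -18.3840
```

`out/model_report.json` holds the full fits (coefficients with 95% Wald
CIs, variance components, log-likelihoods) and every likelihood-ratio
comparison.

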