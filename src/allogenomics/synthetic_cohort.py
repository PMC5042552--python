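"""Synthetic transplant-cohort generator.

Generates donor/recipient genotype pairs and longitudinal clinical tables
with the statistical structure the scoring and association pipeline
assumes, so the whole pipeline can be exercised and validated without any
real exome:

- a panel of biallelic missense sites in synthetic transmembrane genes,
  with minor allele frequencies drawn from a rare-skewed Beta spectrum;
- diploid genotypes under Hardy-Weinberg equilibrium, either independent
  (unrelated pairs) or sharing one haplotype identical-by-descent
  (parent-child pairs), which lowers the expected mismatch score;
- longitudinal eGFR generated by the random-intercept model
  eGFR = intercept + b_age*age + b_AMS*AMS + b_T*T + b_HLA*HLA
         + pair intercept + residual noise.

Default coefficients are the combined-cohort estimates the association
models are expected to recover; noise magnitudes and the mean eGFR level
are generator calibration choices, documented in the package methods note.
Regenerating with the same seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "SyntheticPanel",
    "SyntheticTruth",
    "sample_maf_spectrum",
    "simulate_panel",
    "simulate_pair",
    "pair_contributions",
    "simulate_truth",
    "simulate_cohort",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class SimulationParams:
    """Generator truth for one synthetic cohort.

    Fixed-effect defaults are the combined-cohort model estimates
    (AMS -0.01307 eGFR per score unit; donor age -0.47 per year; time
    -0.24 per month; HLA -0.57 per mismatch). The intercept (102) sets the
    mean eGFR near 55 mL/min/1.73m^2 at the mean covariates; sigma_pair
    and sigma_resid (12 and 8) split the eGFR noise between a per-pair
    baseline and visit-level residuals. Every pair is observed at 12, 24,
    36 and 48 months; alternating pairs get a 60-month visit, giving 239
    observations at the default 53 pairs.
    """

    n_pairs: int = 53
    n_sites: int = 13_000
    n_decoy_sites: int = 0
    sites_per_gene: int = 10
    maf_alpha: float = 0.2
    maf_beta: float = 2.0
    maf_min: float = 0.0005
    maf_max: float = 0.5
    fraction_related: float = 0.5
    beta_ams: float = -0.01307
    beta_age: float = -0.47
    beta_t: float = -0.24
    beta_hla: float = -0.57
    intercept: float = 102.0
    sigma_pair: float = 12.0
    sigma_resid: float = 8.0
    timepoints: tuple[int, ...] = (12, 24, 36, 48)
    extra_timepoints: tuple[int, ...] = (60,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 (the mixed model is unfittable otherwise)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.sigma_pair < 0 or self.sigma_resid < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < maf_min <= maf_max <= 0.5")
        if not 0 <= self.fraction_related <= 1:
            raise ValueError("fraction_related must be in [0, 1]")
        if not self.timepoints or any(t < 0 for t in self.timepoints + self.extra_timepoints):
            raise ValueError("timepoints must be non-empty and non-negative")


@dataclass
class SyntheticPanel:
    """Site-level truth: coordinates, alleles, annotation and MAFs.

    ``scoreable`` marks the sites that belong to the set P (missense in a
    transmembrane gene); decoy sites (synonymous, or missense in a
    non-transmembrane gene) are interleaved to exercise site selection.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_nt: np.ndarray
    alt_nt: np.ndarray
    gene_id: np.ndarray
    transcript_id: np.ndarray
    protein_pos: np.ndarray
    ref_aa: np.ndarray
    alt_aa: np.ndarray
    consequence: np.ndarray
    maf: np.ndarray
    scoreable: np.ndarray
    tm_gene_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class SyntheticTruth:
    """Everything the generator knows: genotypes, true scores, clinical
    covariates, random effects and the noiseless eGFR trajectory."""

    params: SimulationParams
    panel: SyntheticPanel
    donor_gt: np.ndarray  # (n_pairs, n_total_sites) alt-allele counts
    recipient_gt: np.ndarray
    related: np.ndarray  # bool per pair
    ams_distinct: np.ndarray
    ams_allele_copy: np.ndarray
    donor_age: np.ndarray
    hla: np.ndarray
    recipient_sex: np.ndarray
    recipient_race: np.ndarray
    pair_intercept: np.ndarray
    clinical: pd.DataFrame  # includes observed egfr and noiseless egfr_true

    @property
    def pair_ids(self) -> list[str]:
        return [f"pair{i:03d}" for i in range(self.params.n_pairs)]


def sample_maf_spectrum(params: SimulationParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw minor allele frequencies from the rare-skewed Beta spectrum,
    truncated to (maf_min, maf_max) by inverse-CDF sampling."""
    d = stats.beta(params.maf_alpha, params.maf_beta)
    u = rng.uniform(d.cdf(params.maf_min), d.cdf(params.maf_max), size=n)
    return d.ppf(u)


def simulate_panel(params: SimulationParams, rng: Optional[np.random.Generator] = None) -> SyntheticPanel:
    """Build the synthetic site panel.

    ``n_sites`` scoreable missense sites are assigned to synthetic
    transmembrane genes (``sites_per_gene`` each); ``n_decoy_sites`` extra
    sites alternate between synonymous changes in transmembrane genes and
    missense changes in non-transmembrane genes, and are excluded from the
    set P by construction.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_total = params.n_sites + params.n_decoy_sites
    maf = sample_maf_spectrum(params, rng, n_total)

    chrom = np.full(n_total, "1", dtype=object)
    pos = 1000 + 20 * np.arange(n_total)
    ref_idx = rng.integers(0, 4, n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, n_total)) % 4
    ref_nt = np.array([_NT[i] for i in ref_idx], dtype=object)
    alt_nt = np.array([_NT[i] for i in alt_idx], dtype=object)

    ref_aa_idx = rng.integers(0, 20, n_total)
    alt_aa_idx = (ref_aa_idx + rng.integers(1, 20, n_total)) % 20
    ref_aa = np.array([_AA[i] for i in ref_aa_idx], dtype=object)
    alt_aa = np.array([_AA[i] for i in alt_aa_idx], dtype=object)

    gene_id = np.empty(n_total, dtype=object)
    transcript_id = np.empty(n_total, dtype=object)
    protein_pos = np.empty(n_total, dtype=int)
    consequence = np.full(n_total, "missense_variant", dtype=object)
    scoreable = np.zeros(n_total, dtype=bool)

    n_tm_genes = -(-params.n_sites // params.sites_per_gene)
    tm_gene_ids = tuple(f"TMG{g:05d}" for g in range(n_tm_genes))
    for i in range(params.n_sites):
        g = i // params.sites_per_gene
        gene_id[i] = tm_gene_ids[g]
        transcript_id[i] = f"TMT{g:05d}"
        protein_pos[i] = 1 + 7 * (i % params.sites_per_gene)
        scoreable[i] = True
    for j in range(params.n_decoy_sites):
        i = params.n_sites + j
        if j % 2 == 0:
            # synonymous change inside a transmembrane gene
            g = j % n_tm_genes
            gene_id[i] = tm_gene_ids[g]
            transcript_id[i] = f"TMT{g:05d}"
            consequence[i] = "synonymous_variant"
            alt_aa[i] = ref_aa[i]
        else:
            # missense change in a non-transmembrane gene
            gene_id[i] = f"CYT{j:05d}"
            transcript_id[i] = f"CYT{j:05d}T"
        protein_pos[i] = 1 + 7 * (j % params.sites_per_gene)

    return SyntheticPanel(
        chrom=chrom, pos=pos, ref_nt=ref_nt, alt_nt=alt_nt,
        gene_id=gene_id, transcript_id=transcript_id, protein_pos=protein_pos,
        ref_aa=ref_aa, alt_aa=alt_aa, consequence=consequence, maf=maf,
        scoreable=scoreable, tm_gene_ids=tm_gene_ids,
    )


def simulate_pair(
    panel: SyntheticPanel, related: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw donor and recipient genotypes (alt-allele counts 0/1/2).

    Unrelated: both individuals drawn independently under Hardy-Weinberg
    at each site. Related (parent-child, donor = parent): the recipient
    inherits one allele from the donor at every site, the other haplotype
    is drawn from the population frequencies. Sites are unlinked, so the
    transmitted haplotype is an independent pick per site.
    """
    n = len(panel)
    donor_h = rng.random((2, n)) < panel.maf
    donor_gt = donor_h.sum(axis=0).astype(np.int8)
    if related:
        pick = rng.integers(0, 2, n)
        inherited = donor_h[pick, np.arange(n)]
        other = rng.random(n) < panel.maf
        recipient_gt = (inherited.astype(np.int8) + other.astype(np.int8))
    else:
        recipient_gt = ((rng.random((2, n)) < panel.maf).sum(axis=0)).astype(np.int8)
    return donor_gt, recipient_gt


def pair_contributions(
    donor_gt: np.ndarray, recipient_gt: np.ndarray, mode: str = "distinct"
) -> np.ndarray:
    """Vectorized per-site score contributions for biallelic sites, from
    alt-allele counts. Used for generator-side truth tallies."""
    d, r = donor_gt, recipient_gt
    donor_has_ref, donor_has_alt = d < 2, d > 0
    recip_no_ref, recip_no_alt = r == 2, r == 0
    if mode == "distinct":
        return (donor_has_ref & recip_no_ref).astype(np.int64) + (
            donor_has_alt & recip_no_alt
        )
    if mode == "allele-copy":
        return (2 - d).astype(np.int64) * recip_no_ref + d.astype(np.int64) * recip_no_alt
    raise ValueError(f"unknown scoring mode {mode!r}")


def simulate_truth(params: SimulationParams) -> SyntheticTruth:
    """Generate a full cohort in memory: panel, genotypes, true scores and
    the longitudinal clinical table (observed and noiseless eGFR)."""
    rng = np.random.default_rng(params.seed)
    panel = simulate_panel(params, rng)
    n = params.n_pairs

    n_related = int(round(params.fraction_related * n))
    related = np.zeros(n, dtype=bool)
    related[:n_related] = True

    donor_gt = np.empty((n, len(panel)), dtype=np.int8)
    recipient_gt = np.empty((n, len(panel)), dtype=np.int8)
    for i in range(n):
        donor_gt[i], recipient_gt[i] = simulate_pair(panel, bool(related[i]), rng)

    score_mask = panel.scoreable
    ams_distinct = np.array([
        int(pair_contributions(donor_gt[i, score_mask], recipient_gt[i, score_mask], "distinct").sum())
        for i in range(n)
    ])
    ams_allele_copy = np.array([
        int(pair_contributions(donor_gt[i, score_mask], recipient_gt[i, score_mask], "allele-copy").sum())
        for i in range(n)
    ])

    donor_age = stats.truncnorm.rvs(
        (18 - 45) / 12, (75 - 45) / 12, loc=45, scale=12, size=n, random_state=rng
    )
    hla = rng.integers(0, 7, n)
    recipient_sex = np.where(rng.random(n) < 0.5, "male", "female")
    recipient_race = np.where(rng.random(n) < 0.2, "black", "non-black")
    pair_intercept = rng.normal(0.0, params.sigma_pair, n)

    rows = []
    for i in range(n):
        months = list(params.timepoints)
        if i % 2 == 0:
            months += list(params.extra_timepoints)
        for t in months:
            mu = (
                params.intercept
                + params.beta_age * donor_age[i]
                + params.beta_ams * ams_distinct[i]
                + params.beta_t * t
                + params.beta_hla * hla[i]
            )
            obs = mu + pair_intercept[i] + rng.normal(0.0, params.sigma_resid)
            rows.append(
                {
                    "pair_id": f"pair{i:03d}",
                    "months": t,
                    "donor_age": round(float(donor_age[i]), 4),
                    "hla_abdr_mismatches": int(hla[i]),
                    "recipient_sex": recipient_sex[i],
                    "recipient_race": recipient_race[i],
                    "egfr": round(float(obs), 4),
                    "egfr_true": round(float(mu), 4),
                }
            )
    clinical = pd.DataFrame(rows)
    return SyntheticTruth(
        params=params, panel=panel, donor_gt=donor_gt, recipient_gt=recipient_gt,
        related=related, ams_distinct=ams_distinct, ams_allele_copy=ams_allele_copy,
        donor_age=donor_age, hla=hla, recipient_sex=recipient_sex,
        recipient_race=recipient_race, pair_intercept=pair_intercept, clinical=clinical,
    )


# ---------------------------------------------------------------------------
# File output

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=allogenomics-synthetic-cohort
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=RI,Number=1,Type=Integer,Description="Distinct read indices supporting the call">
"""

_GT_STR = ("0/0", "0/1", "1/1")
_AD_STR = ("30,0", "15,15", "0,30")


def _write_vcf(path: Path, panel: SyntheticPanel, sample_gts: dict[str, np.ndarray]) -> None:
    samples = list(sample_gts)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(len(panel)):
            calls = "\t".join(
                f"{_GT_STR[sample_gts[s][j]]}:{_AD_STR[sample_gts[s][j]]}:10" for s in samples
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t.\t{panel.ref_nt[j]}\t{panel.alt_nt[j]}"
                f"\t100\tPASS\t.\tGT:AD:RI\t{calls}\n"
            )


def _write_annotation_tsv(path: Path, panel: SyntheticPanel) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "chrom", "pos", "ref", "alt", "gene_id", "transcript_id",
            "protein_pos", "ref_aa", "alt_aa", "consequence",
        ])
        for j in range(len(panel)):
            w.writerow([
                panel.chrom[j], panel.pos[j], panel.ref_nt[j], panel.alt_nt[j],
                panel.gene_id[j], panel.transcript_id[j], panel.protein_pos[j],
                panel.ref_aa[j], panel.alt_aa[j], panel.consequence[j],
            ])


def simulate_cohort(
    params: SimulationParams,
    out_dir: Union[str, Path],
    combined_vcf: bool = False,
) -> tuple[SyntheticTruth, dict[str, Path]]:
    """Generate a cohort and write every file the scoring and association
    stages consume: per-pair VCFs (two single-sample files, or one
    two-sample file with ``combined_vcf``), annotation TSV, transmembrane
    gene list TSV, pair manifest CSV, clinical CSV and a truth JSON with
    per-pair scores in both modes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(params)
    panel = truth.panel
    paths: dict[str, Path] = {}

    manifest_rows = []
    for i, pid in enumerate(truth.pair_ids):
        donor_sample, recip_sample = f"{pid}_D", f"{pid}_R"
        if combined_vcf:
            vcf = out_dir / f"{pid}.vcf"
            _write_vcf(vcf, panel, {donor_sample: truth.donor_gt[i], recip_sample: truth.recipient_gt[i]})
            donor_vcf = recip_vcf = vcf.name
        else:
            dv, rv = out_dir / f"{pid}_donor.vcf", out_dir / f"{pid}_recipient.vcf"
            _write_vcf(dv, panel, {donor_sample: truth.donor_gt[i]})
            _write_vcf(rv, panel, {recip_sample: truth.recipient_gt[i]})
            donor_vcf, recip_vcf = dv.name, rv.name
        manifest_rows.append(
            {
                "pair_id": pid,
                "donor_sample": donor_sample,
                "recipient_sample": recip_sample,
                "donor_vcf": donor_vcf,
                "recipient_vcf": recip_vcf,
            }
        )

    paths["annotation"] = out_dir / "annotation.tsv"
    _write_annotation_tsv(paths["annotation"], panel)

    paths["tm_genes"] = out_dir / "tm_genes.tsv"
    with open(paths["tm_genes"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Gene stable ID"])
        for g in panel.tm_gene_ids:
            w.writerow([g])

    paths["manifest"] = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)

    paths["clinical"] = out_dir / "clinical.csv"
    truth.clinical.to_csv(paths["clinical"], index=False)

    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "params": asdict(truth.params),
                "pairs": [
                    {
                        "pair_id": pid,
                        "ams_distinct": int(truth.ams_distinct[i]),
                        "ams_allele_copy": int(truth.ams_allele_copy[i]),
                        "related": bool(truth.related[i]),
                        "donor_age": float(truth.donor_age[i]),
                        "hla_abdr_mismatches": int(truth.hla[i]),
                        "pair_intercept": float(truth.pair_intercept[i]),
                    }
                    for i, pid in enumerate(truth.pair_ids)
                ],
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    logger.info("synthetic cohort written to %s (%d pairs, %d sites)", out_dir, params.n_pairs, len(panel))
    return truth, paths
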