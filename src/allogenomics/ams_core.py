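"""The allogenomics mismatch score (AMS).

At each scoreable protein site the donor and recipient each carry two
amino-acid alleles. The site's contribution counts donor amino acids absent
from the recipient genotype at that position — potential non-self epitopes
the graft can display. Contributions lie in {0, 1, 2} and are summed over
the site set P to give the pair's score Δ(recipient, donor). The score is
directional: donor alleles novel to the recipient count, never the reverse.

Two contribution semantics are exposed:

- ``distinct`` (default): the number of *distinct* donor amino acids not in
  the recipient genotype. A donor homozygous for one novel residue
  contributes 1.
- ``allele-copy``: the number of donor allele *copies* (with multiplicity)
  whose amino acid is not in the recipient genotype. The same donor
  contributes 2.

The two modes differ only for a donor homozygous for a novel residue;
allele-copy totals dominate distinct totals everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genotype_io import BOTH_CALLED, PairedGenotype

logger = logging.getLogger(__name__)

__all__ = [
    "MODE_DISTINCT",
    "MODE_ALLELE_COPY",
    "ScoreContribution",
    "AMSResult",
    "MafSummary",
    "site_contribution",
    "compute_ams",
    "maf_summary",
]

MODE_DISTINCT = "distinct"
MODE_ALLELE_COPY = "allele-copy"


@dataclass(frozen=True)
class ScoreContribution:
    """One site's contribution to the score."""

    chrom: str
    pos: int
    gene_id: str
    contribution: int
    novel_donor_aas: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.contribution <= 2:
            raise ValueError(f"contribution must be in {{0,1,2}}, got {self.contribution}")


@dataclass
class AMSResult:
    """Δ(recipient, donor) for one transplant pair, with per-site and
    per-gene detail."""

    pair_id: str
    total: int
    n_sites_considered: int
    n_sites_contributing: int
    per_site: list[ScoreContribution]
    per_gene: dict[str, int]
    mode: str

    def __post_init__(self) -> None:
        if self.total != sum(c.contribution for c in self.per_site):
            raise ValueError("total must equal the sum of per-site contributions")
        if self.n_sites_contributing > self.n_sites_considered:
            raise ValueError("contributing sites cannot exceed considered sites")


@dataclass
class MafSummary:
    """Minor-allele-frequency distribution of contributing sites."""

    mafs: list[float]
    bin_edges: np.ndarray
    counts: np.ndarray
    n_missing: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.mafs)) if self.mafs else float("nan")


def site_contribution(
    recipient_aas: Sequence[str],
    donor_aas: Sequence[str],
    mode: str = MODE_DISTINCT,
) -> int:
    """Contribution of one protein site: donor amino acids absent from the
    recipient's genotype at that site.

    Both genotypes must be diploid (exactly two amino acids). The result is
    0, 1 or 2 in both modes. The reference residue is an ordinary allele: a
    donor homozygous-reference scores against a recipient homozygous for an
    alternate residue.
    """
    if len(recipient_aas) != 2 or len(donor_aas) != 2:
        raise ValueError(
            f"genotypes must carry exactly two alleles, got "
            f"recipient={tuple(recipient_aas)} donor={tuple(donor_aas)}"
        )
    recipient = set(recipient_aas)
    if mode == MODE_DISTINCT:
        return len({a for a in donor_aas if a not in recipient})
    if mode == MODE_ALLELE_COPY:
        return sum(1 for a in donor_aas if a not in recipient)
    raise ValueError(f"unknown scoring mode {mode!r}")


def compute_ams(
    paired_sites: Iterable[PairedGenotype],
    pair_id: str,
    mode: str = MODE_DISTINCT,
) -> AMSResult:
    """Sum per-site contributions over the site set to give Δ(r, d).

    Only sites with both genotypes called are scored; others do not enter
    ``n_sites_considered``. Per-site output is ordered by (chrom, pos) so
    repeated runs diff cleanly; per-gene sums partition the total.
    """
    per_site: list[ScoreContribution] = []
    per_gene: dict[str, int] = {}
    n_considered = 0
    for p in sorted(paired_sites, key=lambda p: (p.site.chrom, p.site.pos)):
        if p.call_status != BOTH_CALLED:
            continue
        n_considered += 1
        recipient = set(p.recipient_aas)
        novel = tuple(sorted(set(a for a in p.donor_aas if a not in recipient)))
        c = site_contribution(p.recipient_aas, p.donor_aas, mode=mode)
        per_site.append(
            ScoreContribution(
                chrom=p.site.chrom,
                pos=p.site.pos,
                gene_id=p.annotation.gene_id,
                contribution=c,
                novel_donor_aas=novel,
            )
        )
        if c:
            per_gene[p.annotation.gene_id] = per_gene.get(p.annotation.gene_id, 0) + c
    total = sum(c.contribution for c in per_site)
    if n_considered == 0:
        logger.warning("pair %s: empty site panel; AMS is 0 but uninformative", pair_id)
    return AMSResult(
        pair_id=pair_id,
        total=total,
        n_sites_considered=n_considered,
        n_sites_contributing=sum(1 for c in per_site if c.contribution > 0),
        per_site=per_site,
        per_gene=per_gene,
        mode=mode,
    )


def maf_summary(
    result: AMSResult,
    maf_table: Mapping[tuple[str, int], float],
    bins: int = 25,
) -> MafSummary:
    """Minor-allele-frequency distribution over the sites that contributed
    to the score (contribution > 0).

    ``maf_table`` maps (chrom, pos) to a population minor allele frequency
    in [0, 0.5]. Contributing sites missing from the table are tallied in
    ``n_missing``, not fatal.
    """
    mafs: list[float] = []
    n_missing = 0
    for c in result.per_site:
        if c.contribution == 0:
            continue
        maf = maf_table.get((c.chrom, c.pos))
        if maf is None:
            n_missing += 1
            continue
        if not 0.0 <= maf <= 0.5:
            raise ValueError(f"MAF must be in [0, 0.5], got {maf} at {c.chrom}:{c.pos}")
        mafs.append(float(maf))
    counts, edges = np.histogram(mafs, bins=bins, range=(0.0, 0.5))
    return MafSummary(mafs=mafs, bin_edges=edges, counts=counts, n_missing=n_missing)
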