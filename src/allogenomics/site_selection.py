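"""Construct the scoreable site set P: missense variant positions in genes
carrying at least one transmembrane segment.

The transmembrane gene list is an input (a Biomart-style TSV export), not a
computation: predicting membrane topology is out of scope, and the panel is
defined at gene level (any transmembrane segment in the gene admits all its
missense sites), not at residue level.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .genotype_io import BOTH_CALLED, PairedGenotype, ProteinAnnotation, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "TransmembraneGeneSet",
    "SitePanel",
    "PanelBuild",
    "ConfigurationError",
    "load_tm_genes",
    "build_panel",
]

DEFAULT_CONSEQUENCES = frozenset({"missense_variant"})

# exclusion reasons
REASON_NON_TM = "non-TM-gene"
REASON_CONSEQUENCE = "consequence-not-admitted"
REASON_CALL_STATUS = "call-status-ineligible"


class ConfigurationError(ValueError):
    """Invalid or empty configuration input."""


@dataclass(frozen=True)
class TransmembraneGeneSet:
    """Deduplicated identifiers of genes with >=1 transmembrane segment."""

    gene_ids: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ConfigurationError("transmembrane gene set must be non-empty")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SitePanel:
    """The admitted site set P with its selection configuration."""

    sites: tuple[tuple[VariantSite, ProteinAnnotation], ...]
    consequences: frozenset[str] = DEFAULT_CONSEQUENCES
    gene_set_label: str = ""

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class PanelBuild:
    """Result of panel construction: the panel, the paired genotypes that
    passed selection (in site order), and exclusion tallies by reason."""

    panel: SitePanel
    retained: list[PairedGenotype]
    exclusions: Counter = field(default_factory=Counter)

    @property
    def n_input(self) -> int:
        return len(self.retained) + sum(self.exclusions.values())


def load_tm_genes(
    tsv_path: Union[str, Path], column: Optional[str] = None
) -> TransmembraneGeneSet:
    """Load a transmembrane gene list from a Biomart-style TSV export
    (header row, tab-separated, one gene-id column).

    ``column`` names the gene-id column; when omitted, the first column
    whose header mentions "gene" is used, falling back to the sole column
    of a single-column file.
    """
    tsv_path = Path(tsv_path)
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None:
            raise ConfigurationError(f"gene list {tsv_path} is empty")
        if column is None:
            candidates = [c for c in reader.fieldnames if "gene" in c.lower()]
            if candidates:
                column = candidates[0]
            elif len(reader.fieldnames) == 1:
                column = reader.fieldnames[0]
            else:
                raise ConfigurationError(
                    f"gene list {tsv_path} has no recognizable gene-id column "
                    f"(columns: {reader.fieldnames})"
                )
        elif column not in reader.fieldnames:
            raise ConfigurationError(f"gene list {tsv_path} lacks column {column!r}")
        ids = {row[column].strip() for row in reader if row[column] and row[column].strip()}
    if not ids:
        raise ConfigurationError(f"gene list {tsv_path} contains no gene ids")
    logger.info("loaded %d transmembrane gene ids from %s", len(ids), tsv_path)
    return TransmembraneGeneSet(gene_ids=frozenset(ids), source_label=str(tsv_path))


def build_panel(
    paired: Iterable[PairedGenotype],
    tm: TransmembraneGeneSet,
    consequences: frozenset[str] = DEFAULT_CONSEQUENCES,
) -> PanelBuild:
    """Filter paired genotypes down to the site set P.

    A site is admitted iff its gene is in the transmembrane set, its
    consequence is among the admitted classes (missense only by default),
    and both genotypes are called. Exclusions are tallied by the first
    failing reason, so ``len(retained) + sum(exclusions) == n input sites``.
    """
    retained: list[PairedGenotype] = []
    exclusions: Counter = Counter()
    for p in paired:
        if p.annotation.gene_id not in tm:
            exclusions[REASON_NON_TM] += 1
        elif p.annotation.consequence not in consequences:
            exclusions[REASON_CONSEQUENCE] += 1
        elif p.call_status != BOTH_CALLED:
            exclusions[REASON_CALL_STATUS] += 1
        else:
            retained.append(p)
    retained.sort(key=lambda p: (p.site.chrom, p.site.pos))
    panel = SitePanel(
        sites=tuple((p.site, p.annotation) for p in retained),
        consequences=consequences,
        gene_set_label=tm.source_label,
    )
    logger.info(
        "panel: %d sites admitted, exclusions: %s", len(panel), dict(exclusions)
    )
    return PanelBuild(panel=panel, retained=retained, exclusions=exclusions)
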