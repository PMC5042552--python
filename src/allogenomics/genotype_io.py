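"""Read annotated VCFs for donor and recipient samples and emit paired,
amino-acid-level genotypes per protein site.

The scoring pipeline starts from genotype calls in VCF v4.x (plain or
bgzip+tabix). Each diploid call is translated to an unordered pair of
one-letter amino acids using a protein annotation source: either a side-car
TSV table or VEP-style CSQ strings declared in the VCF header. Genotype-call
quality filters (minimum per-allele read support, minimum number of distinct
read indices) are applied before pairing; calls failing a filter are demoted
to no-calls rather than dropped, so coverage asymmetry between the two
samples remains visible downstream.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "ProteinAnnotation",
    "SampleGenotype",
    "PairedGenotype",
    "AnnotationTable",
    "AnnotationError",
    "MissingSampleError",
    "VcfParseError",
    "read_sample_vcf",
    "apply_quality_filters",
    "parse_csq_entry",
    "parse_annotation",
    "pair_genotypes",
    "write_paired_tsv",
    "read_paired_tsv",
    "CONSEQUENCE_SEVERITY",
]

# Call status vocabulary for a paired site.
BOTH_CALLED = "both-called"
DONOR_ONLY = "donor-only"
RECIPIENT_ONLY = "recipient-only"
NEITHER = "neither"

# No-call handling policies for sites observed in only one sample.
REQUIRE_BOTH = "require-both"
ASSUME_HOM_REF = "assume-hom-ref"

# Protein-level consequence terms ordered from most to least severe; used to
# pick one annotation when a site is annotated on several transcripts.
CONSEQUENCE_SEVERITY = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "protein_altering_variant",
    "splice_region_variant",
    "synonymous_variant",
)

_AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}


class MissingSampleError(KeyError):
    """Requested sample id is not present in the VCF."""


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


class AnnotationError(ValueError):
    """An annotation source entry is malformed."""


@dataclass(frozen=True)
class VariantSite:
    """One genomic position with its reference and alternate alleles."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.alts or self.ref in self.alts:
            raise ValueError(f"alts must be non-empty and distinct from ref at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)


@dataclass(frozen=True)
class ProteinAnnotation:
    """Protein-level consequence of a variant site on one transcript.

    ``alt_aa`` holds one amino acid per alternate allele, in the allele
    order of the site.
    """

    gene_id: str
    transcript_id: str
    protein_pos: int
    ref_aa: str
    alt_aa: tuple[str, ...]
    consequence: str
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.consequence == "missense_variant" and all(a == self.ref_aa for a in self.alt_aa):
            raise ValueError(
                f"missense annotation at {self.gene_id}:{self.protein_pos} must change the amino acid"
            )

    def aa_for_allele(self, allele_index: int) -> str:
        """Amino acid encoded by VCF allele index (0 = ref, k = k-th alt)."""
        if allele_index == 0:
            return self.ref_aa
        return self.alt_aa[allele_index - 1]

    @property
    def severity_rank(self) -> int:
        try:
            return CONSEQUENCE_SEVERITY.index(self.consequence)
        except ValueError:
            return len(CONSEQUENCE_SEVERITY)


@dataclass(frozen=True)
class SampleGenotype:
    """Diploid genotype call for one sample at one site.

    ``alleles`` is a pair of allele indices into (ref, *alts), or ``None``
    for a no-call. ``support`` holds per-allele read support (indexed like
    the alleles, ref first) when the VCF provides it (AD), else ``None``.
    ``distinct_read_indices`` mirrors the genotype caller's RI field.
    """

    sample_id: str
    site: VariantSite
    alleles: Optional[tuple[int, int]]
    support: Optional[tuple[int, ...]] = None
    distinct_read_indices: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            n_alleles = 1 + len(self.site.alts)
            for a in self.alleles:
                if not 0 <= a < n_alleles:
                    raise ValueError(
                        f"allele index {a} out of range at {self.site.chrom}:{self.site.pos}"
                    )
        if self.support is not None and any(s < 0 for s in self.support):
            raise ValueError("read support must be >= 0")
        if self.distinct_read_indices is not None and self.distinct_read_indices < 0:
            raise ValueError("distinct_read_indices must be >= 0")

    @property
    def is_called(self) -> bool:
        return self.alleles is not None


@dataclass(frozen=True)
class PairedGenotype:
    """Donor and recipient genotypes at one annotated protein site,
    resolved to unordered amino-acid pairs (sorted tuples)."""

    pair_id: str
    site: VariantSite
    annotation: ProteinAnnotation
    recipient_aas: Optional[tuple[str, str]]
    donor_aas: Optional[tuple[str, str]]
    call_status: str

    def __post_init__(self) -> None:
        for aas in (self.recipient_aas, self.donor_aas):
            if aas is None:
                continue
            valid = {self.annotation.ref_aa, *self.annotation.alt_aa}
            for aa in aas:
                if aa not in valid:
                    raise ValueError(
                        f"amino acid {aa!r} not among annotated alleles at "
                        f"{self.site.chrom}:{self.site.pos}"
                    )


# ---------------------------------------------------------------------------
# VCF reading


def _site_from_variant(v) -> VariantSite:
    return VariantSite(chrom=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT))


def read_sample_vcf(vcf_path: Union[str, Path], sample_id: str) -> Iterator[SampleGenotype]:
    """Stream one :class:`SampleGenotype` per VCF record for ``sample_id``.

    Multiallelic records are preserved with their ordered alternate
    alleles; missing genotypes (``./.``) become no-call markers.

    Raises
    ------
    MissingSampleError
        if ``sample_id`` is not a sample of the VCF.
    VcfParseError
        if a record cannot be interpreted (reported with its position).
    """
    vcf_path = str(vcf_path)
    vcf = VCF(vcf_path)
    try:
        if sample_id not in vcf.samples:
            raise MissingSampleError(
                f"sample {sample_id!r} not in {vcf_path} (samples: {vcf.samples})"
            )
        idx = vcf.samples.index(sample_id)
        for record_no, v in enumerate(vcf, start=1):
            try:
                site = _site_from_variant(v)
                gt = v.genotypes[idx]  # [allele1, allele2, phased]
                a1, a2 = int(gt[0]), int(gt[1])
                alleles = None if a1 < 0 or a2 < 0 else (a1, a2)
                support = _format_ints(v, "AD", idx)
                ri = _format_ints(v, "RI", idx)
                yield SampleGenotype(
                    sample_id=sample_id,
                    site=site,
                    alleles=alleles,
                    support=support,
                    distinct_read_indices=ri[0] if ri else None,
                )
            except (ValueError, IndexError, TypeError) as exc:
                raise VcfParseError(
                    f"malformed record #{record_no} at {v.CHROM}:{v.POS} in {vcf_path}: {exc}"
                ) from exc
    finally:
        vcf.close()


def _format_ints(v, tag: str, idx: int) -> Optional[tuple[int, ...]]:
    try:
        arr = v.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    vals = tuple(int(x) for x in arr[idx] if int(x) >= 0)
    return vals or None


# ---------------------------------------------------------------------------
# Quality filtering


def apply_quality_filters(
    g: SampleGenotype,
    min_support: int = 3,
    min_distinct_read_indices: int = 3,
    stats: Optional[Counter] = None,
) -> SampleGenotype:
    """Demote a call to no-call unless every non-reference allele passes the
    read-support thresholds.

    A genotype is retained iff each non-reference allele it carries has
    read support >= ``min_support`` and the call's distinct read index count
    is >= ``min_distinct_read_indices``. Homozygous-reference calls carry no
    alternate allele and always pass. Calls lacking support metadata cannot
    be assessed and are retained (tallied under ``"unassessed"``).
    Rejected calls are demoted to no-call, never dropped, so the pairing
    stage still sees the site.
    """
    if min_support < 0 or min_distinct_read_indices < 0:
        raise ValueError("filter thresholds must be >= 0")
    if stats is None:
        stats = Counter()
    if not g.is_called:
        stats["no_call_in"] += 1
        return g
    non_ref = [a for a in g.alleles if a != 0]
    if not non_ref:
        stats["retained"] += 1
        return g
    if g.support is None and g.distinct_read_indices is None:
        stats["unassessed"] += 1
        return g
    ok = True
    if g.support is not None:
        for a in set(non_ref):
            if a >= len(g.support) or g.support[a] < min_support:
                ok = False
    if g.distinct_read_indices is not None and g.distinct_read_indices < min_distinct_read_indices:
        ok = False
    if ok:
        stats["retained"] += 1
        return g
    stats["demoted"] += 1
    logger.debug(
        "demoting %s at %s:%s to no-call (support=%s, RI=%s)",
        g.sample_id, g.site.chrom, g.site.pos, g.support, g.distinct_read_indices,
    )
    return replace(g, alleles=None)


# ---------------------------------------------------------------------------
# Annotation sources

_HGVSP_RE = re.compile(r"p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=|\*)")


def parse_csq_entry(
    site: VariantSite, csq_value: str, csq_fields: Sequence[str]
) -> list[ProteinAnnotation]:
    """Parse one record's CSQ INFO value into protein annotations.

    ``csq_fields`` is the pipe-separated field layout declared in the VCF
    header (``Format: Allele|Consequence|...``). One annotation is emitted
    per (transcript, alternate allele) entry that changes the protein;
    entries without a protein-level change (e.g. synonymous) are skipped.
    """
    fields = [f.strip() for f in csq_fields]
    required = {"Allele", "Consequence"}
    missing = required - set(fields)
    if missing:
        raise AnnotationError(f"CSQ header lacks required field(s): {sorted(missing)}")
    out: list[ProteinAnnotation] = []
    for entry in csq_value.split(","):
        parts = entry.split("|")
        if len(parts) != len(fields):
            raise AnnotationError(
                f"CSQ entry at {site.chrom}:{site.pos} has {len(parts)} fields, "
                f"header declares {len(fields)} (field layout mismatch)"
            )
        rec = dict(zip(fields, parts))
        consequence = rec["Consequence"].split("&")[0]
        allele = rec["Allele"]
        try:
            alt_index = site.alts.index(allele)
        except ValueError:
            # VEP trims shared prefixes for indels; only SNV-style alleles
            # are resolved here, others are skipped.
            continue
        parsed = _csq_protein_change(rec, site)
        if parsed is None:
            continue
        protein_pos, ref_aa, alt_aa = parsed
        if consequence == "synonymous_variant" or ref_aa == alt_aa:
            continue
        alt_aas = ["?"] * len(site.alts)
        alt_aas[alt_index] = alt_aa
        # unannotated alternates of this transcript entry keep ref_aa
        alt_aas = [ref_aa if a == "?" else a for a in alt_aas]
        out.append(
            ProteinAnnotation(
                gene_id=rec.get("Gene", ""),
                transcript_id=rec.get("Feature", ""),
                protein_pos=protein_pos,
                ref_aa=ref_aa,
                alt_aa=tuple(alt_aas),
                consequence=consequence,
                canonical=rec.get("CANONICAL", "") == "YES",
            )
        )
    return out


def _csq_protein_change(rec: Mapping[str, str], site: VariantSite):
    """Extract (protein_pos, ref_aa, alt_aa) from a CSQ entry dict, trying
    the Amino_acids/Protein_position pair first, then HGVSp."""
    aa = rec.get("Amino_acids", "")
    ppos = rec.get("Protein_position", "")
    if aa and "/" in aa and ppos:
        ref_aa, alt_aa = aa.split("/", 1)
        try:
            return int(ppos.split("-")[0]), ref_aa, alt_aa
        except ValueError as exc:
            raise AnnotationError(f"bad Protein_position field {ppos!r}") from exc
    hgvsp = rec.get("HGVSp", "")
    m = _HGVSP_RE.search(hgvsp)
    if m:
        ref3, pos, alt3 = m.groups()
        ref_aa = _AA_3TO1.get(ref3)
        if ref_aa is None:
            raise AnnotationError(f"unknown amino acid code in HGVSp field {hgvsp!r}")
        if alt3 == "=":
            alt_aa = ref_aa
        elif alt3 == "*":
            alt_aa = "*"
        else:
            alt_aa = _AA_3TO1.get(alt3)
            if alt_aa is None:
                raise AnnotationError(f"unknown amino acid code in HGVSp field {hgvsp!r}")
        return int(pos), ref_aa, alt_aa
    return None


class AnnotationTable:
    """Site-keyed protein annotation lookup.

    Built either from a TSV table (columns: chrom, pos, ref, alt, gene_id,
    transcript_id, protein_pos, ref_aa, alt_aa, consequence) or by scanning
    a VEP-annotated VCF's CSQ strings.
    """

    TSV_COLUMNS = (
        "chrom", "pos", "ref", "alt", "gene_id", "transcript_id",
        "protein_pos", "ref_aa", "alt_aa", "consequence",
    )

    def __init__(self, entries: Optional[Mapping[tuple, list[ProteinAnnotation]]] = None):
        self._by_site: dict[tuple, list[ProteinAnnotation]] = dict(entries or {})

    def add(self, site: VariantSite, ann: ProteinAnnotation) -> None:
        self._by_site.setdefault(site.key, []).append(ann)

    def lookup(self, site: VariantSite) -> list[ProteinAnnotation]:
        return list(self._by_site.get(site.key, []))

    def __len__(self) -> int:
        return len(self._by_site)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "AnnotationTable":
        table = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            if reader.fieldnames is None:
                raise AnnotationError(f"annotation table {path} is empty")
            missing = set(cls.TSV_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise AnnotationError(
                    f"annotation table {path} lacks column(s): {sorted(missing)}"
                )
            # rows for the same (chrom,pos,ref) with different alts are merged
            # into multi-alt sites keyed per exact allele set later; here each
            # row describes one (site, alt, transcript).
            staged: dict[tuple, dict] = {}
            for row in reader:
                key = (row["chrom"], int(row["pos"]), row["ref"], row["transcript_id"])
                slot = staged.setdefault(key, {"alts": [], "rows": []})
                if row["alt"] not in slot["alts"]:
                    slot["alts"].append(row["alt"])
                slot["rows"].append(row)
            for (chrom, pos, ref, _tx), slot in staged.items():
                alts = tuple(slot["alts"])
                site = VariantSite(chrom=chrom, pos=pos, ref=ref, alts=alts)
                row0 = slot["rows"][0]
                alt_aas = [row0["ref_aa"]] * len(alts)
                for row in slot["rows"]:
                    alt_aas[alts.index(row["alt"])] = row["alt_aa"]
                table.add(
                    site,
                    ProteinAnnotation(
                        gene_id=row0["gene_id"],
                        transcript_id=row0["transcript_id"],
                        protein_pos=int(row0["protein_pos"]),
                        ref_aa=row0["ref_aa"],
                        alt_aa=tuple(alt_aas),
                        consequence=row0["consequence"],
                        canonical=row0.get("canonical", "").lower() in ("1", "true", "yes"),
                    ),
                )
        return table

    @classmethod
    def from_vep_vcf(cls, path: Union[str, Path]) -> "AnnotationTable":
        """Collect CSQ annotations from a VEP-annotated VCF."""
        vcf = VCF(str(path))
        try:
            fields = _csq_fields_from_header(vcf)
            table = cls()
            for v in vcf:
                csq = v.INFO.get("CSQ")
                if csq is None:
                    continue
                site = _site_from_variant(v)
                for ann in parse_csq_entry(site, csq, fields):
                    table.add(site, ann)
        finally:
            vcf.close()
        return table


def _csq_fields_from_header(vcf: VCF) -> list[str]:
    for h in vcf.header_iter():
        info = h.info()
        if info.get("ID") == "CSQ":
            desc = info.get("Description", "")
            m = re.search(r"Format:\s*([^\"]+)", desc)
            if m:
                return m.group(1).strip().split("|")
    raise AnnotationError("VCF header does not declare a CSQ INFO field layout")


def parse_annotation(site: VariantSite, source: AnnotationTable) -> list[ProteinAnnotation]:
    """All protein annotations for ``site``; empty if the site has no
    protein-level consequence in the source."""
    return source.lookup(site)


def select_annotation(annotations: Sequence[ProteinAnnotation]) -> Optional[ProteinAnnotation]:
    """Pick one annotation per physical site: canonical transcript if
    flagged, else most severe consequence, ties broken by transcript id."""
    if not annotations:
        return None
    return sorted(
        annotations,
        key=lambda a: (not a.canonical, a.severity_rank, a.transcript_id),
    )[0]


# ---------------------------------------------------------------------------
# Pairing


def _translate(alleles: tuple[int, int], ann: ProteinAnnotation) -> tuple[str, str]:
    return tuple(sorted(ann.aa_for_allele(a) for a in alleles))  # type: ignore[return-value]


def pair_genotypes(
    donor: Iterable[SampleGenotype],
    recipient: Iterable[SampleGenotype],
    annotations: AnnotationTable,
    policy: str = REQUIRE_BOTH,
    pair_id: str = "",
    stats: Optional[Counter] = None,
) -> list[PairedGenotype]:
    """Join donor and recipient genotype streams over the union of their
    sites and translate calls to amino-acid pairs.

    Under ``require-both`` (default) a site observed or called in only one
    sample keeps its true call status and is later skipped by the scorer.
    Under ``assume-hom-ref`` the missing side is completed as homozygous
    reference, reflecting that exome assays imply the reference allele at
    covered positions without a variant call.

    Sites carried by either sample but absent from the annotation source
    are excluded (tallied under ``"unannotated"``), since they cannot enter
    the scoreable site set.
    """
    if policy not in (REQUIRE_BOTH, ASSUME_HOM_REF):
        raise ValueError(f"unknown no-call policy {policy!r}")
    if stats is None:
        stats = Counter()

    donor_by_site: dict[tuple, SampleGenotype] = {g.site.key: g for g in donor}
    recip_by_site: dict[tuple, SampleGenotype] = {g.site.key: g for g in recipient}
    out: list[PairedGenotype] = []
    for key in sorted(set(donor_by_site) | set(recip_by_site)):
        d = donor_by_site.get(key)
        r = recip_by_site.get(key)
        site = (d or r).site
        ann = select_annotation(parse_annotation(site, annotations))
        if ann is None:
            stats["unannotated"] += 1
            logger.debug("no annotation for site %s:%s; excluded", site.chrom, site.pos)
            continue

        d_called = d is not None and d.is_called
        r_called = r is not None and r.is_called
        donor_aas = _translate(d.alleles, ann) if d_called else None
        recip_aas = _translate(r.alleles, ann) if r_called else None

        if d_called and r_called:
            status = BOTH_CALLED
        elif d_called:
            status = DONOR_ONLY
        elif r_called:
            status = RECIPIENT_ONLY
        else:
            status = NEITHER

        if policy == ASSUME_HOM_REF and status in (DONOR_ONLY, RECIPIENT_ONLY):
            hom_ref = (ann.ref_aa, ann.ref_aa)
            donor_aas = donor_aas or hom_ref
            recip_aas = recip_aas or hom_ref
            status = BOTH_CALLED
            stats["completed_hom_ref"] += 1

        stats[status] += 1
        out.append(
            PairedGenotype(
                pair_id=pair_id,
                site=site,
                annotation=ann,
                recipient_aas=recip_aas,
                donor_aas=donor_aas,
                call_status=status,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV interchange

_PAIRED_TSV_HEADER = (
    "pair_id", "chrom", "pos", "ref", "alts", "gene_id", "transcript_id",
    "protein_pos", "ref_aa", "alt_aa", "consequence", "canonical",
    "recipient_aas", "donor_aas", "call_status",
)


def _aas_to_str(aas: Optional[tuple[str, str]]) -> str:
    return "".join(aas) if aas is not None else "."


def _aas_from_str(s: str) -> Optional[tuple[str, str]]:
    if s == ".":
        return None
    return tuple(sorted(s))  # type: ignore[return-value]


def write_paired_tsv(paired: Iterable[PairedGenotype], path: Union[str, Path]) -> None:
    """Serialize paired genotypes to the TSV interchange format."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PAIRED_TSV_HEADER)
        for p in paired:
            w.writerow([
                p.pair_id, p.site.chrom, p.site.pos, p.site.ref, ",".join(p.site.alts),
                p.annotation.gene_id, p.annotation.transcript_id,
                p.annotation.protein_pos, p.annotation.ref_aa,
                ",".join(p.annotation.alt_aa), p.annotation.consequence,
                int(p.annotation.canonical),
                _aas_to_str(p.recipient_aas), _aas_to_str(p.donor_aas), p.call_status,
            ])


def read_paired_tsv(path: Union[str, Path]) -> list[PairedGenotype]:
    """Inverse of :func:`write_paired_tsv`."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            site = VariantSite(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                alts=tuple(row["alts"].split(",")),
            )
            ann = ProteinAnnotation(
                gene_id=row["gene_id"], transcript_id=row["transcript_id"],
                protein_pos=int(row["protein_pos"]), ref_aa=row["ref_aa"],
                alt_aa=tuple(row["alt_aa"].split(",")),
                consequence=row["consequence"], canonical=bool(int(row["canonical"])),
            )
            out.append(
                PairedGenotype(
                    pair_id=row["pair_id"], site=site, annotation=ann,
                    recipient_aas=_aas_from_str(row["recipient_aas"]),
                    donor_aas=_aas_from_str(row["donor_aas"]),
                    call_status=row["call_status"],
                )
            )
    return out
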