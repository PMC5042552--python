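import textwrap
from pathlib import Path

import numpy as np
import pytest

from allogenomics.genotype_io import PairedGenotype, ProteinAnnotation, VariantSite
from allogenomics.synthetic_cohort import SimulationParams, simulate_cohort

AA = "ACDEFGHIKLMNPQRSTVWY"

VCF_META = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##contig=<ID=1>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##FORMAT=<ID=RI,Number=1,Type=Integer,Description="Distinct read indices">
    """
)


def write_vcf(path: Path, body: str, samples=("S1",), extra_header: str = "") -> Path:
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_META + extra_header + cols + "\n" + textwrap.dedent(body))
    return path


def random_paired_genotypes(rng: np.random.Generator, n: int, pair_id: str = "p0"):
    """Fuzzed paired genotypes over random biallelic missense sites."""
    out = []
    for i in range(n):
        ref_aa = AA[rng.integers(0, 20)]
        alt_aa = AA[(AA.index(ref_aa) + rng.integers(1, 20)) % 20]
        ann = ProteinAnnotation(
            gene_id=f"G{rng.integers(0, 37):03d}",
            transcript_id=f"T{i:04d}",
            protein_pos=int(rng.integers(1, 500)),
            ref_aa=ref_aa,
            alt_aa=(alt_aa,),
            consequence="missense_variant",
        )
        site = VariantSite(chrom="1", pos=100 + 10 * i, ref="A", alts=("C",))
        pool = (ref_aa, alt_aa)
        recip = tuple(sorted(pool[j] for j in rng.integers(0, 2, 2)))
        donor = tuple(sorted(pool[j] for j in rng.integers(0, 2, 2)))
        out.append(
            PairedGenotype(
                pair_id=pair_id, site=site, annotation=ann,
                recipient_aas=recip, donor_aas=donor, call_status="both-called",
            )
        )
    return out


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small written cohort shared by IO-heavy tests: 6 pairs, 250
    scoreable sites plus 12 decoys."""
    out = tmp_path_factory.mktemp("cohort")
    params = SimulationParams(n_pairs=6, n_sites=250, n_decoy_sites=12, seed=11)
    truth, paths = simulate_cohort(params, out)
    return params, truth, paths, out
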