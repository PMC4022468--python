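from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##contig=<ID=2,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FILTER=<ID=LowQual,Description="low quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
1\t300\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2\t0/0\t0/1
1\t400\t.\tT\tA\t.\tPASS\t.\tGT\t./.\t0/1\t1/1
2\t150\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
"""

TOY_POPMAP = """\
sample_id\tpopulation\tcontinent
S1\tCHB\tASN
S2\tCHB\tASN
S3\tCEU\tEUR
"""


@pytest.fixture
def toy_cohort(tmp_path: Path) -> tuple[Path, Path]:
    """A 5-site, 3-sample cohort: multi-allelic site, missing GT, two chromosomes."""
    vcf = tmp_path / "toy.vcf"
    popmap = tmp_path / "popmap.tsv"
    vcf.write_text(TOY_VCF)
    popmap.write_text(TOY_POPMAP)
    return vcf, popmap


@pytest.fixture
def toy_reference(tmp_path: Path) -> Path:
    """Reference FASTA with known CpG context at specific positions."""
    fasta = tmp_path / "ref.fa"
    fasta.write_text(">1\nACGTAATT\n")
    return fasta
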