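import textwrap
from pathlib import Path

import numpy as np
import pytest

from bgscan.io_formats import AncestralSource


def _write_fasta(path: Path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i: i + 60] + "\n")


@pytest.fixture()
def toy_reference(tmp_path):
    """60 bp chr1 reference: background 'A' with the bases the toy VCF
    needs; position 31 is 'G' so position 30 sits in a CpG context."""
    seq = list("A" * 60)
    seq[20 - 1] = "C"
    seq[25 - 1] = "T"
    seq[30 - 1] = "C"
    seq[31 - 1] = "G"
    seq[40 - 1] = "T"
    seq[45 - 1] = "G"
    path = tmp_path / "ref.fa"
    _write_fasta(path, "chr1", "".join(seq))
    return path


@pytest.fixture()
def toy_vcf(tmp_path):
    """8-record VCF: 1 triallelic, 1 with a missing genotype, 1 that cannot
    be polarized, 1 CpG-context site and 4 clean polymorphic SNVs."""
    body = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=60>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
        chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0
        chr1\t15\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2
        chr1\t20\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.
        chr1\t25\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0
        chr1\t30\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0
        chr1\t40\t.\tT\tC\t.\tPASS\t.\tGT\t1/1\t0/1
        chr1\t45\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1
        chr1\t50\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1
        """)
    path = tmp_path / "toy.vcf"
    path.write_text(body)
    return path


@pytest.fixture()
def toy_ancestral(toy_reference):
    """Ancestral FASTA equal to the reference: record at pos 25 (REF A,
    ALT G, ancestral T) then fails polarization."""
    return AncestralSource(fasta_path=toy_reference)


@pytest.fixture()
def simple_map(tmp_path):
    """Two-interval map: 2.0 cM/Mb on [1, 1e6+1), 0.5 cM/Mb beyond."""
    path = tmp_path / "map.txt"
    path.write_text(
        "chrom\tpos\trate\tcM\n"
        "chr1\t1\t2.0\t0.0\n"
        "chr1\t1000001\t0.5\t2.0\n"
        "chr1\t2000001\t0.0\t2.5\n")
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
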