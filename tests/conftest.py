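import numpy as np
import pytest

from moals.synthetic_data import SimulationConfig, generate_cohort

# Six variant-consequence records: three pass every filter, one is
# non-canonical, one too common (AF 0.02), one lacks a gene symbol.
TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|SYMBOL|CANONICAL|AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tA\tT\t.\t.\tCSQ=T|frameshift_variant|GENE1|YES|0.001\tGT\t0/1\t0/0
1\t200\t.\tC\tG\t.\t.\tCSQ=G|stop_gained|GENE2|YES|\tGT\t1/1\t0/1
1\t300\t.\tG\tA\t.\t.\tCSQ=A|splice_donor_variant|GENE3|YES|0.005\tGT\t0/0\t0/1
1\t400\t.\tT\tC\t.\t.\tCSQ=C|missense_variant|GENE4||0.001\tGT\t0/1\t0/0
1\t500\t.\tA\tG\t.\t.\tCSQ=G|stop_gained|GENE5|YES|0.02\tGT\t0/1\t0/0
1\t600\t.\tC\tT\t.\t.\tCSQ=T|frameshift_variant||YES|0.001\tGT\t0/1\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(n_samples=200, n_cases=150, n_controls=50,
                           n_genes_expression=120, n_genes_burden=30,
                           n_burden_signal_genes=15, seed=2)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
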