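import pytest

from sibseg.synthetic_data import SimConfig, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort used across modules (fixed seed)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The same cohort serialized into the pipeline's input formats."""
    outdir = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(cohort, outdir)
    return paths


def write_text(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture
def tiny_vcf(tmp_path):
    """Single hom-alt record with AD=0,42."""
    return write_text(tmp_path / "tiny.vcf", """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT:DP:AD:GQ\t1/1:42:0,42:60
""")


@pytest.fixture
def multiallelic_vcf(tmp_path):
    """One triallelic record, three samples."""
    return write_text(tmp_path / "multi.vcf", """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t500\t.\tC\tA,T\t.\tPASS\t.\tGT:AD\t0/1:10,5,0\t1/2:0,7,8\t2/2:0,0,20
""")
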