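import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bn_cohort():
    """Default synthetic cohort: 3 populations x 50 samples, 2000 loci, F=0.1."""
    from mipca import SimulationSpec, simulate_balding_nichols

    return simulate_balding_nichols(SimulationSpec(seed=2024))


@pytest.fixture(scope="session")
def bn_pipeline(bn_cohort):
    """Standardized matrix, decomposition and 2-axis embedding of the cohort."""
    from mipca import decompose, filter_loci, impute_missing, make_embedding, standardize

    gm, report = filter_loci(bn_cohort)
    gm = impute_missing(gm)
    sm = standardize(gm)
    decomp = decompose(sm, 10)
    emb = make_embedding(decomp, [1, 2], population_labels=gm.population_labels)
    return {"gm": gm, "report": report, "sm": sm, "decomp": decomp, "emb": emb}


@pytest.fixture()
def tiny_tsv(tmp_path):
    """3-sample, 4-locus genotype TSV with one missing entry."""
    p = tmp_path / "tiny.geno.tsv"
    p.write_text(
        "sample_id\tl1\tl2\tl3\tl4\n"
        "s1\t0\t1\t2\t0\n"
        "s2\t2\t1\t0\tNA\n"
        "s3\t1\t0\t1\t2\n"
    )
    return p


@pytest.fixture()
def mini_vcf(tmp_path):
    """Four-record VCF covering het/hom/missing/half-call/multiallelic cases."""
    p = tmp_path / "mini.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1|1\t0/1\n"
        "1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t./.\t0/1\t0/.\n"
        "1\t400\trs4\tT\tA,C\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\n"
    )
    return p


@pytest.fixture()
def mini_traw(tmp_path):
    """PLINK traw fixture whose second locus counts the majority allele."""
    p = tmp_path / "mini.traw"
    p.write_text(
        "CHR\tSNP\t(C)M\tPOS\tCOUNTED\tALT\tF1_I1\tF2_I2\tF3_I3\n"
        "1\tsnpA\t0\t100\tG\tA\t0\t1\t2\n"
        "1\tsnpB\t0\t200\tT\tC\t2\t2\t1\n"
        "1\tsnpC\t0\t300\tA\tC\t0\tNA\t1\n"
    )
    return p


def random_orthonormal(m, k, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((m, max(k, 1))))
    return q[:, :k]
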