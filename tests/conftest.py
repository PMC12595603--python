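import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


TOY_GFF3 = """##gff-version 3
Chr1\ttoy\tgene\t1001\t2000\t.\t+\t.\tID=gA;Name=ALPHA
Chr1\ttoy\tmRNA\t1001\t2000\t.\t+\t.\tID=gA.t1;Parent=gA
Chr1\ttoy\texon\t1001\t2000\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
Chr1\ttoy\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=gA.t1.u5;Parent=gA.t1
Chr1\ttoy\tCDS\t1101\t1900\t.\t+\t.\tID=gA.t1.c1;Parent=gA.t1
Chr1\ttoy\tthree_prime_UTR\t1901\t2000\t.\t+\t.\tID=gA.t1.u3;Parent=gA.t1
Chr1\ttoy\tgene\t5001\t6200\t.\t-\t.\tID=gB;Name=BETA
Chr1\ttoy\tmRNA\t5001\t6200\t.\t-\t.\tID=gB.t1;Parent=gB
Chr1\ttoy\texon\t5001\t5500\t.\t-\t.\tID=gB.t1.e1;Parent=gB.t1
Chr1\ttoy\texon\t5801\t6200\t.\t-\t.\tID=gB.t1.e2;Parent=gB.t1
Chr1\ttoy\tthree_prime_UTR\t5001\t5200\t.\t-\t.\tID=gB.t1.u3;Parent=gB.t1
Chr1\ttoy\tCDS\t5201\t5500\t.\t-\t.\tID=gB.t1.c1;Parent=gB.t1
Chr1\ttoy\tCDS\t5801\t6100\t.\t-\t.\tID=gB.t1.c2;Parent=gB.t1
Chr1\ttoy\tfive_prime_UTR\t6101\t6200\t.\t-\t.\tID=gB.t1.u5;Parent=gB.t1
Chr2\ttoy\tgene\t101\t700\t.\t+\t.\tID=gC
Chr2\ttoy\tmRNA\t101\t700\t.\t+\t.\tID=gC.t1;Parent=gC
Chr2\ttoy\texon\t101\t700\t.\t+\t.\tID=gC.t1.e1;Parent=gC.t1
Chr2\ttoy\tfive_prime_UTR\t101\t150\t.\t+\t.\tID=gC.t1.u5;Parent=gC.t1
Chr2\ttoy\tCDS\t151\t600\t.\t+\t.\tID=gC.t1.c1;Parent=gC.t1
Chr2\ttoy\tthree_prime_UTR\t601\t700\t.\t+\t.\tID=gC.t1.u3;Parent=gC.t1
"""


@pytest.fixture(scope="session")
def toy_gff3() -> str:
    return TOY_GFF3


@pytest.fixture(scope="session")
def toy_catalog(toy_gff3):
    from mirmeth.annotation import load_annotation

    return load_annotation(toy_gff3, {"Chr1": 100_000, "Chr2": 50_000})


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic bundle shared by read-only tests."""
    from mirmeth.synthetic import SimConfig, generate

    return generate(SimConfig(seed=20240521, n_genes=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(94281)
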