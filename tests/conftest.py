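import pytest

from gen2vcf.fixtures import FixtureSpec, generate_fixture


@pytest.fixture
def tiny_fixture(tmp_path):
    """8 variants x 3 samples with some missing genotypes, 6-column layout."""
    return generate_fixture(
        FixtureSpec(n_variants=8, n_samples=3, seed=11, missing_rate=0.15),
        tmp_path,
    )


@pytest.fixture
def gen_lines():
    """Three hand-written, well-formed 6-column GEN lines (N=2)."""
    return (
        "1 snp1 rs1 1000 A G 1 0 0 0 1 0\n"
        "1 snp2 rs2 2000 C T 0 0 1 0.25 0.5 0.25\n"
        "1 snp3 rs3 3000 G A 0.406 0.212 0.382 0 0 0\n"
    )
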