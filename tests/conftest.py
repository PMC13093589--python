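import numpy as np
import pytest

import recipcross as rc


@pytest.fixture(scope="session")
def design15():
    return rc.simulate_design(15)


@pytest.fixture(scope="session")
def null_data(design15):
    """A no-effect simulation: 2000 genes, 120 samples."""
    cfg = rc.SimulationConfig.null(seed=11)
    counts, truth = rc.simulate_counts(cfg, design15, np.random.default_rng(11))
    return counts, truth


@pytest.fixture(scope="session")
def planted_data(design15):
    """Strong planted ancestry effects (300 genes, 75% up in HH)."""
    cfg = rc.SimulationConfig(
        seed=21, n_genes=2000, n_ancestry_genes=300,
        n_maternal_genes=0, n_paternal_genes=0,
    )
    counts, truth = rc.simulate_counts(cfg, design15, np.random.default_rng(21))
    return counts, truth


@pytest.fixture()
def toy_vcf(tmp_path):
    """Hand-coded VCF: 3 samples x 5 biallelic loci + 1 multiallelic.

    Expected 0/1/2/missing coding (rows = samples A, B, C):
        locus1  locus2  locus3  locus4  locus5
    A     0       1       2       .       1
    B     1       1       0       2       0
    C     2       0       1       1       .
    """
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=chr1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC",
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0",
            "chr1\t300\t.\tC\tA\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1",
            "chr1\t350\t.\tC\tA,G\t.\tPASS\t.\tGT\t0/1\t1/2\t0/0",
            "chr1\t400\t.\tT\tG\t.\tPASS\t.\tGT\t./.\t1/1\t0/1",
            "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t./.",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text + "\n")
    expected = np.array(
        [
            [0, 1, 2, -1, 1],
            [1, 1, 0, 2, 0],
            [2, 0, 1, 1, -1],
        ],
        dtype=np.int8,
    )
    return path, expected
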