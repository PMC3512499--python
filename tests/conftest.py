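import numpy as np
import pytest

from svmix.admixture_simulator import SyntheticPanelSpec, generate_synthetic_panels

TINY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def tiny_pop_table(tmp_path):
    path = tmp_path / "pops.tsv"
    path.write_text("s1\tA\ns2\tB\n")
    return path


@pytest.fixture(scope="session")
def small_panel():
    """Two well-separated Balding-Nichols populations, 1000 SNPs."""
    spec = SyntheticPanelSpec(n_pops=2, haplotypes_per_pop=20, n_snps=1000,
                              fst_target=0.2, chrom_length_morgans=1.0, seed=11)
    panel, gmap = generate_synthetic_panels(spec)
    return panel, gmap


@pytest.fixture(scope="session")
def separable_panel():
    """Two populations fixed for opposite alleles at every SNP."""
    from svmix.haplotype_io import GeneticMap, HaplotypePanel

    n_snps, n_per_pop = 200, 6
    alleles = np.vstack([
        np.ones((n_per_pop, n_snps), dtype=np.int8),
        -np.ones((n_per_pop, n_snps), dtype=np.int8),
    ])
    bp = 1 + np.arange(n_snps, dtype=np.int64) * 1000
    panel = HaplotypePanel(
        alleles=alleles,
        sample_ids=[f"p{p}_s{i // 2}|{i % 2}" for p in (0, 1)
                    for i in range(n_per_pop)],
        snp_ids=np.array([f"snp{j}" for j in range(n_snps)], dtype=object),
        chrom=np.array(["1"] * n_snps, dtype=object),
        bp_pos=bp,
        labels=np.repeat([1, 2], n_per_pop),
        population_names=["A", "B"],
        encoded=True,
        alt_is_major=np.zeros(n_snps, dtype=bool),
    )
    gmap = GeneticMap({"1": (np.array([bp[0], bp[-1]]), np.array([0.0, 100.0]))})
    panel.annotate_genetic_positions(gmap)
    return panel, gmap
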