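import numpy as np
import pytest

import hildscan as h
from hildscan.genotypes import GenotypeMatrix


def make_random_panel(n, m, seed, maf_low=0.1, maf_high=0.9, n_chromosomes=5):
    """Independent bi-allelic markers at random frequencies (no LD)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, m)
    codes = (rng.random((n, m)) < p).astype(np.int8)
    ids = np.array([f"i{k:04d}" for k in range(n)], dtype=object)
    return GenotypeMatrix(codes, ids, h.make_marker_map(m, seed=seed, n_chromosomes=n_chromosomes))


@pytest.fixture(scope="session")
def fig1():
    """Balanced four-class scenario with perfect P4 tagging of Q."""
    G, y = h.make_fig1_scenario(n_per_class=5, seed=0)
    idx = {mid: k for k, mid in enumerate(G.markers.marker_id)}
    return G, y, idx


@pytest.fixture(scope="session")
def complex_locus():
    """The hidden linked-block scenario at study scale (n = 340)."""
    return h.make_complex_locus_scenario(n=340, seed=1)


@pytest.fixture()
def toy_vcf(tmp_path):
    """20 inbred samples, 5 records: 2 clean SNPs, a rare SNP at the MAF
    boundary, a site with one heterozygote, an indel and a multi-allelic
    site (both skipped)."""
    samples = [f"S{k:02d}" for k in range(20)]
    rows = []
    gt_a = ["1/1"] * 10 + ["0/0"] * 10                      # MAF 0.5
    gt_b = ["1/1"] + ["0/0"] * 19                            # MAF 0.05 (boundary)
    gt_c = ["0/1"] + ["1/1"] * 8 + ["0/0"] * 11              # one het
    gt_d = ["0/0"] * 15 + ["1/1"] * 5                        # MAF 0.25
    rows.append(("1", 100, "snpA", "A", "T", gt_a))
    rows.append(("1", 200, "snpB", "C", "G", gt_b))
    rows.append(("2", 300, "snpC", "G", "A", gt_c))
    rows.append(("2", 400, "indel", "GT", "G", gt_d))
    rows.append(("2", 500, "snpD", "T", "C", gt_d))
    path = tmp_path / "toy.vcf"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n##contig=<ID=2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, gts in rows:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    return path
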