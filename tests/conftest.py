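import numpy as np
import pytest

from histoqtl.simulate import SimConfig, simulate_cohort



@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort with a strong planted genetic effect (n=400, L=16, v=5%)."""
    cfg = SimConfig(n=400, L=16, v=0.05, seed=11)
    g, F, E = simulate_cohort(cfg)
    return cfg, g, F, E


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose embeddings carry no genetic signal (v=0)."""
    cfg = SimConfig(n=300, L=12, v=0.0, seed=5)
    g, F, E = simulate_cohort(cfg)
    return cfg, g, F, E


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_vcf(path, samples, records):
    """Write a minimal plain-text VCF; records are (chrom, pos, id, ref, alt, gts)."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, vid, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path
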