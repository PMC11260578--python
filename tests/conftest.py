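import numpy as np
import pytest

from accessout import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """60 x 300 NB matrix with latent structure, no planted outliers."""
    cfg = SimulationConfig(seed=11, n_samples=60, n_regions=300)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def planted_sim():
    """100 x 1000 matrix with ~50 planted outliers and known truth."""
    cfg = SimulationConfig(
        seed=5, n_samples=100, n_regions=1000, plant_rate=2.5e-4
    )
    return simulate_counts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_counts(bam_path, peaks, min_mapq=10):
    """Independent all-pairs read/peak overlap oracle."""
    import pysam

    counts = np.zeros(len(peaks), dtype=int)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            rs, re = read.reference_start, read.reference_end
            chrom = read.reference_name
            for j, peak in enumerate(peaks):
                if peak.chrom == chrom and rs < peak.end and peak.start < re:
                    counts[j] += 1
                    break  # merged peaks: a read overlaps at most one
    return counts
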