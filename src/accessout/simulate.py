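"""Synthetic fixtures: NB count matrices with latent structure and planted
outliers, tiny alignment/peak fixtures, and a toy annotation bundle.

Everything is deterministic given a seed and emits the same formats as
real inputs, so the whole package is testable offline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import CountMatrix, GenomicRegion, PeakSet, write_bed


@dataclass
class SimulationConfig:
    n_samples: int = 60
    n_regions: int = 300
    q_true: int = 5
    latent_sd: float = 0.4
    base_log_mean: float = float(np.log(150.0))
    base_log_sd: float = 0.6
    size_factor_range: tuple[float, float] = (0.4, 2.5)
    dispersion_range: tuple[float, float] = (50.0, 500.0)
    confounder_levels: int = 0
    confounder_sd: float = 0.0
    plant_rate: float = 0.0
    plant_log_amp_mean: float = 3.0
    plant_log_amp_sd: float = 1.0
    seed: int = 0


def _toy_peaks(n_regions: int, region_len: int = 400, gap: int = 600) -> PeakSet:
    """Tile regions over two ~1 Mb chromosomes."""
    regions = []
    per_chrom = (n_regions + 1) // 2
    for j in range(n_regions):
        chrom = "chr1" if j < per_chrom else "chr2"
        k = j if j < per_chrom else j - per_chrom
        start = 1000 + k * (region_len + gap)
        regions.append(GenomicRegion(chrom, start, start + region_len))
    return PeakSet(regions=regions, min_gap=200)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, dict]:
    """NB counts with low-rank log-mean structure and planted outliers.

    Generative model: ``k_ij ~ NB(mean = exp(H_i W + nbar_j) * s_i,
    dispersion r_j)`` with optional categorical-confounder effects and
    outliers planted on the log scale (signed log-normal amplitude times
    the region's log-scale sd).  The truth bundle records the planted
    mask, dispersions, size factors and the true rank.
    """
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n_samples, config.n_regions, config.q_true

    h = rng.normal(size=(n, q))
    w = rng.normal(scale=config.latent_sd, size=(q, p))
    x = h @ w

    meta = None
    if config.confounder_levels > 1:
        batch = rng.integers(config.confounder_levels, size=n)
        effects = rng.normal(
            scale=config.confounder_sd, size=(config.confounder_levels, p)
        )
        x = x + effects[batch]
        meta = pd.DataFrame({"batch": pd.Categorical(batch.astype(str))})

    nbar = rng.normal(config.base_log_mean, config.base_log_sd, size=p)
    sf = rng.uniform(*config.size_factor_range, size=n)
    lo, hi = config.dispersion_range
    disp = np.exp(rng.uniform(np.log(lo), np.log(hi), size=p))

    mask = np.zeros((n, p), dtype=np.int8)
    if config.plant_rate > 0:
        u = rng.random((n, p))
        mask[u < config.plant_rate] = 1
        mask[(u >= config.plant_rate) & (u < 2 * config.plant_rate)] = -1
        sigma = x.std(axis=0)
        sigma = np.maximum(sigma, 0.1)  # planted effects never vanish
        amp = np.exp(
            rng.normal(config.plant_log_amp_mean, config.plant_log_amp_sd, size=(n, p))
        )
        x = x + sigma[None, :] * amp * mask

    # cap keeps planted amplitudes from overflowing the samplers
    mu = np.minimum(np.exp(x + nbar[None, :]) * sf[:, None], 1e7)
    # NB(mean mu, size r) as a gamma-Poisson mixture
    lam = rng.gamma(shape=disp[None, :], scale=mu / disp[None, :])
    counts = rng.poisson(lam)

    if meta is not None:
        meta.index = [f"s{i}" for i in range(n)]
    cm = CountMatrix(
        counts=counts.astype(np.int64),
        regions=_toy_peaks(p),
        sample_ids=[f"s{i}" for i in range(n)],
        sample_meta=meta,
    )
    truth = {
        "mask": mask,
        "dispersions": disp,
        "size_factors": sf,
        "q_true": q,
        "region_log_means": nbar,
        "latent": h,
        "loadings": w,
    }
    return cm, truth


@dataclass
class AlignmentFixture:
    bam_path: str
    bed_path: str
    peaks: PeakSet
    depths: np.ndarray
    n_low_mapq: int
    n_decoy: int


def simulate_alignment_fixture(
    peaks: PeakSet,
    depths: np.ndarray,
    outdir: str,
    read_len: int = 50,
    n_low_mapq: int = 0,
    n_decoy: int = 0,
    seed: int = 0,
    name: str = "sample",
) -> AlignmentFixture:
    """Write a coordinate-sorted, indexed BAM whose per-region overlap
    counts equal ``depths`` exactly (at min_mapq <= 60).

    ``n_low_mapq`` extra reads (MAPQ 3) are placed inside random regions
    and ``n_decoy`` reads in inter-peak gaps; neither changes counts at
    the default MAPQ cutoff.
    """
    import pysam

    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=np.int64)
    if len(depths) != len(peaks):
        raise ValueError("depths length must match number of peaks")

    chrom_len: dict[str, int] = {}
    for r in peaks:
        chrom_len[r.chrom] = max(chrom_len.get(r.chrom, 0), r.end + 10_000)
    refs = list(chrom_len)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in refs],
    }

    reads: list[tuple[str, int, int]] = []  # (chrom, start, mapq)
    for j, region in enumerate(peaks):
        for _ in range(int(depths[j])):
            hi = max(region.end - read_len, region.start)
            start = int(rng.integers(region.start, hi + 1))
            reads.append((region.chrom, start, 60))
    regions = list(peaks)
    for _ in range(n_low_mapq):
        region = regions[int(rng.integers(len(regions)))]
        hi = max(region.end - read_len, region.start)
        reads.append((region.chrom, int(rng.integers(region.start, hi + 1)), 3))
    by_chrom = peaks.by_chrom()
    for _ in range(n_decoy):
        chrom = refs[int(rng.integers(len(refs)))]
        regs = by_chrom.get(chrom, [])
        # place fully inside a gap, clear of every peak by > read_len
        for _attempt in range(100):
            start = int(rng.integers(0, chrom_len[chrom] - read_len))
            span = GenomicRegion(chrom, start, start + read_len)
            if not any(span.overlaps(r) for r in regs):
                reads.append((chrom, start, 60))
                break

    reads.sort(key=lambda t: (refs.index(t[0]), t[1]))
    os.makedirs(outdir, exist_ok=True)
    bam_path = os.path.join(outdir, f"{name}.bam")
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i, (chrom, start, mapq) in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read{i}"
            a.query_sequence = "A" * read_len
            a.flag = 0
            a.reference_id = refs.index(chrom)
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = f"{read_len}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            bam.write(a)
    pysam.index(bam_path)
    bed_path = os.path.join(outdir, "peaks.bed")
    write_bed(peaks, bed_path)
    return AlignmentFixture(
        bam_path=bam_path,
        bed_path=bed_path,
        peaks=peaks,
        depths=depths,
        n_low_mapq=n_low_mapq,
        n_decoy=n_decoy,
    )


@dataclass
class AnnotationFixture:
    gtf_path: str
    mark_paths: dict[str, str]
    contacts_path: str
    peaks: PeakSet
    expected_classes: dict[str, str]
    power_exponent: float
    power_intercept: float


def simulate_annotation_fixture(outdir: str, seed: int = 0) -> AnnotationFixture:
    """Toy genome with genes, engineered marks and power-law contacts.

    The six peaks cover every class: promoter, active enhancer (proximal
    and distal), poised enhancer, and unannotated.  The contact table
    follows ``score = exp(b0) * d ** b1`` with a known exponent.
    """
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)

    # gene A: chr1:10000-30000 (+); gene B: chr2:50000-80000 (-)
    gtf_path = os.path.join(outdir, "genes.gtf")
    with open(gtf_path, "w") as fh:
        fh.write(
            'chr1\ttoy\tgene\t10001\t30000\t.\t+\t.\tgene_id "GENEA"; gene_name "GENEA";\n'
            'chr1\ttoy\ttranscript\t10001\t30000\t.\t+\t.\tgene_id "GENEA"; transcript_id "GENEA.1";\n'
            'chr1\ttoy\tfive_prime_utr\t10001\t10200\t.\t+\t.\tgene_id "GENEA"; transcript_id "GENEA.1";\n'
            'chr2\ttoy\tgene\t50001\t80000\t.\t-\t.\tgene_id "GENEB"; gene_name "GENEB";\n'
            'chr2\ttoy\ttranscript\t50001\t80000\t.\t-\t.\tgene_id "GENEB"; transcript_id "GENEB.1";\n'
            'chr2\ttoy\tfive_prime_utr\t79801\t80000\t.\t-\t.\tgene_id "GENEB"; transcript_id "GENEB.1";\n'
        )

    peaks = PeakSet(
        regions=[
            GenomicRegion("chr1", 9800, 10300),  # promoter of GENEA (TSS 10000)
            GenomicRegion("chr1", 15000, 15500),  # active enhancer inside gene body
            GenomicRegion("chr1", 200000, 200500),  # active enhancer, distal
            GenomicRegion("chr1", 400000, 400500),  # poised enhancer, distal
            GenomicRegion("chr1", 600000, 600500),  # unannotated
            GenomicRegion("chr2", 79800, 80300),  # promoter of GENEB (TSS 79999)
        ],
        min_gap=200,
    )
    expected_classes = {
        peaks[0].name: "promoter",
        peaks[1].name: "active_enhancer",
        peaks[2].name: "active_enhancer",
        peaks[3].name: "poised_enhancer",
        peaks[4].name: "unannotated",
        peaks[5].name: "promoter",
    }

    marks = {
        "H3K4me3": [peaks[0], peaks[5]],
        "H3K27ac": [peaks[1], peaks[2]],
        "H3K4me1": [peaks[1], peaks[2], peaks[3]],
    }
    mark_paths = {}
    for mark, regions in marks.items():
        path = os.path.join(outdir, f"{mark}.bed")
        padded = [GenomicRegion(r.chrom, max(r.start - 50, 0), r.end + 50) for r in regions]
        write_bed(padded, path)
        mark_paths[mark] = path

    # power-law contacts between all same-chromosome peak pairs
    b1 = -1.0
    b0 = float(np.log(5e4))
    rows = []
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i], peaks[j]
            if a.chrom != b.chrom:
                continue
            d = abs(a.midpoint - b.midpoint)
            score = float(np.exp(b0) * max(d, 5000) ** b1)
            rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end, score))
    contacts_path = os.path.join(outdir, "contacts.tsv")
    pd.DataFrame(rows).to_csv(contacts_path, sep="\t", header=False, index=False)

    return AnnotationFixture(
        gtf_path=gtf_path,
        mark_paths=mark_paths,
        contacts_path=contacts_path,
        peaks=peaks,
        expected_classes=expected_classes,
        power_exponent=b1,
        power_intercept=b0,
    )
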