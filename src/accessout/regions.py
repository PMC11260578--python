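"""Genomic regions, peak merging, read counting and replication filters.

Coordinates are BED convention throughout: 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative coordinate in {self.name}")
        if self.start >= self.end:
            raise ValueError(f"malformed interval (start >= end): {self.name}")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """An ordered, non-overlapping collection of regions.

    Adjacent same-chromosome regions are separated by at least ``min_gap``
    bp after :func:`merge_close_regions`.
    """

    regions: list[GenomicRegion] = field(default_factory=list)
    min_gap: int = 200

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicRegion]]:
        out: dict[str, list[GenomicRegion]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            },
            index=self.names,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_gap: int = 200) -> "PeakSet":
        regions = [
            GenomicRegion(str(c), int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        return cls(regions=regions, min_gap=min_gap)


def read_bed(path: str) -> list[GenomicRegion]:
    """Read a BED3+/narrowPeak file; extra columns are ignored."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line with <3 fields: {line!r}")
            regions.append(GenomicRegion(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def merge_close_regions(
    regions: Sequence[GenomicRegion], min_gap: int = 200
) -> PeakSet:
    """Sort regions and union any same-chromosome pair with gap < ``min_gap``.

    The gap between consecutive regions is ``next.start - prev.end``;
    merging applies under strict inequality, so a gap of exactly
    ``min_gap`` is preserved.  Idempotent and order-invariant.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    for r in regions:
        if not isinstance(r, GenomicRegion):
            raise TypeError("expected GenomicRegion instances")
    ordered = sorted(regions)
    merged: list[GenomicRegion] = []
    for r in ordered:
        if merged and merged[-1].chrom == r.chrom and r.start - merged[-1].end < min_gap:
            prev = merged[-1]
            merged[-1] = GenomicRegion(prev.chrom, prev.start, max(prev.end, r.end))
        else:
            merged.append(r)
    return PeakSet(regions=merged, min_gap=min_gap)


@dataclass
class CountMatrix:
    """Samples x regions integer read counts with region coordinates."""

    counts: np.ndarray
    regions: PeakSet
    sample_ids: list[str]
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (samples x regions)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match counts rows")
        if self.counts.shape[1] != len(self.regions):
            raise ValueError("regions length does not match counts columns")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Regions as rows (``chrom:start-end``), samples as columns."""
        return pd.DataFrame(
            self.counts.T, index=self.regions.names, columns=self.sample_ids
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sample_meta: pd.DataFrame | None = None
    ) -> "CountMatrix":
        regions = []
        for name in df.index:
            chrom, span = str(name).rsplit(":", 1)
            start, end = span.split("-")
            regions.append(GenomicRegion(chrom, int(start), int(end)))
        return cls(
            counts=df.to_numpy().T,
            regions=PeakSet(regions=regions),
            sample_ids=[str(c) for c in df.columns],
            sample_meta=sample_meta,
        )

    @classmethod
    def from_tsv(cls, path: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float64),
            obs=(
                self.sample_meta.copy()
                if self.sample_meta is not None
                else pd.DataFrame(index=self.sample_ids)
            ),
            var=self.regions.to_frame(),
        )
        adata.obs_names = self.sample_ids
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "CountMatrix":
        var = adata.var
        regions = PeakSet.from_frame(var)
        meta = adata.obs if adata.obs.shape[1] else None
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(
            counts=np.asarray(X).round().astype(np.int64),
            regions=regions,
            sample_ids=[str(s) for s in adata.obs_names],
            sample_meta=meta,
        )

    def subset_regions(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        kept = [r for r, keep in zip(self.regions.regions, mask) if keep]
        return CountMatrix(
            counts=self.counts[:, mask],
            regions=PeakSet(regions=kept, min_gap=self.regions.min_gap),
            sample_ids=list(self.sample_ids),
            sample_meta=self.sample_meta,
        )


class MultiPeakReadWarning(UserWarning):
    """A read overlapped more than one peak (gap assumption violated)."""


def count_reads(
    alignments,
    peaks: PeakSet,
    min_mapq: int = 10,
    drop_duplicates: bool = False,
) -> np.ndarray:
    """Count aligned reads overlapping each region of ``peaks``.

    ``alignments`` is an open :class:`pysam.AlignmentFile` or a path to a
    coordinate-sorted, indexed BAM.  A read is counted when its aligned
    reference span overlaps a region by >= 1 bp; with merged peaks (gap >
    read length) a read can overlap at most one region.  Reads violating
    the gap assumption are assigned to the first overlapping peak and a
    warning is emitted.  Single sweep per chromosome; memory linear in
    the number of peaks.
    """
    import pysam

    own = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments, "rb")
        own = True
    try:
        header = alignments.header.to_dict()
        so = header.get("HD", {}).get("SO", "unknown")
        if so != "coordinate":
            raise ValueError(f"BAM must be coordinate-sorted (SO={so!r})")
        bam_chroms = set(alignments.references)

        counts = np.zeros(len(peaks), dtype=np.int64)
        offsets: dict[str, int] = {}
        by_chrom = peaks.by_chrom()
        off = 0
        for chrom, regs in by_chrom.items():
            offsets[chrom] = off
            off += len(regs)
        # peaks grouped by chromosome keep the global column order
        order = {r: i for i, r in enumerate(peaks.regions)}

        n_multi = 0
        for chrom, regs in by_chrom.items():
            if chrom not in bam_chroms:
                warnings.warn(
                    f"chromosome {chrom!r} absent from BAM header; zero counts",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            starts = np.array([r.start for r in regs])
            ends = np.array([r.end for r in regs])
            idx = 0  # first peak whose end is beyond the current read start
            n = len(regs)
            for read in alignments.fetch(chrom):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if drop_duplicates and read.is_duplicate:
                    continue
                rs = read.reference_start
                re = read.reference_end  # CIGAR-consumed reference span
                if re is None:
                    continue
                while idx < n and ends[idx] <= rs:
                    idx += 1
                if idx < n and starts[idx] < re:
                    counts[order[regs[idx]]] += 1
                    if idx + 1 < n and starts[idx + 1] < re:
                        n_multi += 1
        if n_multi:
            warnings.warn(
                f"{n_multi} read(s) overlapped more than one peak; each was "
                "assigned to the first overlapping peak",
                MultiPeakReadWarning,
                stacklevel=2,
            )
        return counts
    finally:
        if own:
            alignments.close()


def count_many(
    bam_paths: Sequence[str],
    peaks: PeakSet,
    sample_ids: Sequence[str] | None = None,
    min_mapq: int = 10,
    drop_duplicates: bool = False,
) -> CountMatrix:
    """Count reads for several BAM files into one CountMatrix."""
    import os

    if sample_ids is None:
        sample_ids = [os.path.splitext(os.path.basename(p))[0] for p in bam_paths]
    rows = [
        count_reads(p, peaks, min_mapq=min_mapq, drop_duplicates=drop_duplicates)
        for p in bam_paths
    ]
    return CountMatrix(
        counts=np.vstack(rows), regions=peaks, sample_ids=list(sample_ids)
    )


def filter_regions(
    counts: CountMatrix,
    high_count: int = 100,
    min_reads: int = 2,
    min_fraction: float = 0.5,
) -> tuple[CountMatrix, np.ndarray]:
    """Replication filter: keep a region iff it reaches ``high_count`` reads
    in at least one sample AND has >= ``min_reads`` reads in at least
    ``min_fraction`` of samples (both thresholds inclusive)."""
    if counts.n_regions == 0 or counts.n_samples == 0:
        raise ValueError("empty count matrix")
    k = counts.counts
    high = k.max(axis=0) >= high_count
    replicated = (k >= min_reads).mean(axis=0) >= min_fraction
    mask = high & replicated
    return counts.subset_regions(mask), mask
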