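"""Functional annotation of accessible regions.

Classifies regions from histone-mark intervals and a gene model
(promoter / active enhancer / poised enhancer / unannotated, proximal /
distal), tests outlier-pair proximity enrichment, scores Hi-C contacts
between regions, fits a distance-controlled power regression, and
computes activity-by-contact (ABC) scores.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .regions import GenomicRegion, PeakSet, read_bed

PROMOTER_WINDOW = 1000
UPSTREAM_PROXIMAL = 10_000
DOWNSTREAM_PROXIMAL = 2_000
DEFAULT_BIN_SIZE = 5_000
DEFAULT_VICINITY = 1_000_000
ENRICHMENT_DISTANCES = (10_000, 100_000, 500_000, 1_000_000)


# ---------------------------------------------------------------------------
# interval machinery
# ---------------------------------------------------------------------------

class IntervalIndex:
    """Merged, sorted intervals per chromosome for O(log n) overlap tests."""

    def __init__(self, intervals: list[GenomicRegion]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cummax_ends: dict[str, np.ndarray] = {}
        self._payload: dict[str, list] = {}
        by_chrom: dict[str, list[GenomicRegion]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            ends = np.array([iv.end for iv in ivs])
            self._starts[chrom] = np.array([iv.start for iv in ivs])
            self._ends[chrom] = ends
            self._cummax_ends[chrom] = np.maximum.accumulate(ends)
            self._payload[chrom] = ivs

    def overlapping(self, region: GenomicRegion) -> list[GenomicRegion]:
        starts = self._starts.get(region.chrom)
        if starts is None:
            return []
        ends = self._ends[region.chrom]
        # intervals may overlap each other: scan all with start < region.end
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return [
            self._payload[region.chrom][i]
            for i in range(hi)
            if ends[i] > region.start
        ]

    def any_overlap(self, region: GenomicRegion) -> bool:
        starts = self._starts.get(region.chrom)
        if starts is None:
            return False
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return hi > 0 and self._cummax_ends[region.chrom][hi - 1] > region.start


# ---------------------------------------------------------------------------
# gene model (GTF)
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneModel:
    genes: list[Gene]
    utr5: list[tuple[str, int, int, str]] = field(default_factory=list)
    # (chrom, start, end, gene_id), 0-based half-open

    def tss_points(self) -> list[tuple[str, int, str]]:
        return [(g.chrom, g.tss, g.gene_id) for g in self.genes]


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str) -> GeneModel:
    """Parse a GENCODE-dialect GTF into a gene model.

    1-based inclusive coordinates are converted to 0-based half-open.
    Transcript start sites are strand-aware; ``five_prime_utr``/``UTR``
    features are collected per gene.
    """
    genes: dict[str, Gene] = {}
    utr5: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            start0, end0 = int(start) - 1, int(end)
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id", "")
            if feature == "gene":
                genes[gid] = Gene(gid, chrom, start0, end0, strand)
            elif feature in ("five_prime_utr", "five_prime_UTR", "UTR"):
                utr5.append((chrom, start0, end0, gid))
    return GeneModel(genes=list(genes.values()), utr5=utr5)


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    region_id: str
    klass: str  # promoter | active_enhancer | poised_enhancer | unannotated
    locality: str  # proximal | distal | not_applicable
    linked_genes: list[str] = field(default_factory=list)


def _load_marks(marks: dict[str, object]) -> dict[str, IntervalIndex]:
    out = {}
    for name, src in marks.items():
        if src is None:
            continue
        if isinstance(src, str):
            out[name] = IntervalIndex(read_bed(src))
        elif isinstance(src, IntervalIndex):
            out[name] = src
        else:
            out[name] = IntervalIndex(list(src))
    return out


def classify_regions(
    peaks: PeakSet,
    marks: dict[str, object],
    genes: GeneModel | None = None,
    promoter_window: int = PROMOTER_WINDOW,
) -> list[RegionAnnotation]:
    """Classify each region from histone marks and the gene model.

    promoter: H3K4me3 AND (within ``promoter_window`` of a TSS or
    overlapping a 5' UTR) — takes precedence; active enhancer: H3K4me1
    AND H3K27ac; poised enhancer: H3K4me1 only; otherwise unannotated.
    Enhancers are proximal if inside a gene body or within 10 kb
    upstream / 2 kb downstream of a gene (strand-aware), else distal.
    """
    idx = _load_marks(marks)
    missing = [m for m in ("H3K4me3", "H3K27ac", "H3K4me1") if m not in idx]
    if missing:
        unreachable = {
            "H3K4me3": "promoter",
            "H3K27ac": "active_enhancer",
            "H3K4me1": "active_enhancer/poised_enhancer",
        }
        warnings.warn(
            f"missing mark track(s) {missing}; unreachable classes: "
            f"{[unreachable[m] for m in missing]}",
            UserWarning,
        )

    tss_index = None
    utr_index = None
    gene_body = None
    proximal_zone = None
    if genes is not None:
        tss_iv, utr_iv, body_iv, prox_iv = [], [], [], []
        for g in genes.genes:
            t = g.tss
            tss_iv.append(
                _tagged(g.chrom, max(t - promoter_window, 0), t + promoter_window + 1, g.gene_id)
            )
            body_iv.append(_tagged(g.chrom, g.start, g.end, g.gene_id))
            if g.strand == "+":
                up = (max(g.start - UPSTREAM_PROXIMAL, 0), g.start)
                down = (g.end, g.end + DOWNSTREAM_PROXIMAL)
            else:
                up = (g.end, g.end + UPSTREAM_PROXIMAL)
                down = (max(g.start - DOWNSTREAM_PROXIMAL, 0), g.start)
            for s, e in (up, down, (g.start, g.end)):
                if s < e:
                    prox_iv.append(_tagged(g.chrom, s, e, g.gene_id))
        for chrom, s, e, gid in genes.utr5:
            utr_iv.append(_tagged(chrom, s, e, gid))
        tss_index = IntervalIndex(tss_iv)
        utr_index = IntervalIndex(utr_iv)
        gene_body = IntervalIndex(body_iv)
        proximal_zone = IntervalIndex(prox_iv)

    out = []
    for region in peaks:
        has_me3 = "H3K4me3" in idx and idx["H3K4me3"].any_overlap(region)
        has_ac = "H3K27ac" in idx and idx["H3K27ac"].any_overlap(region)
        has_me1 = "H3K4me1" in idx and idx["H3K4me1"].any_overlap(region)

        promoter_genes: list[str] = []
        if has_me3 and tss_index is not None:
            promoter_genes = sorted(
                {iv.gene_id for iv in tss_index.overlapping(region)}
                | {iv.gene_id for iv in utr_index.overlapping(region)}
            )
        if promoter_genes:
            out.append(RegionAnnotation(region.name, "promoter", "not_applicable", promoter_genes))
            continue
        if has_me1:
            klass = "active_enhancer" if has_ac else "poised_enhancer"
            linked: list[str] = []
            locality = "distal"
            if proximal_zone is not None:
                linked = sorted({iv.gene_id for iv in proximal_zone.overlapping(region)})
                if linked:
                    locality = "proximal"
            out.append(RegionAnnotation(region.name, klass, locality, linked))
            continue
        out.append(RegionAnnotation(region.name, "unannotated", "not_applicable", []))
    return out


class _TaggedRegion(GenomicRegion):
    pass


def _tagged(chrom: str, start: int, end: int, gene_id: str) -> "_TaggedRegion":
    r = _TaggedRegion(chrom, start, end)
    object.__setattr__(r, "gene_id", gene_id)
    return r


def annotations_to_frame(annotations: list[RegionAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [a.region_id for a in annotations],
            "class": [a.klass for a in annotations],
            "locality": [a.locality for a in annotations],
            "genes": [",".join(a.linked_genes) for a in annotations],
        }
    )


# ---------------------------------------------------------------------------
# outlier-pair proximity enrichment
# ---------------------------------------------------------------------------

def outlier_pair_enrichment(
    peaks: PeakSet,
    is_outlier: np.ndarray,
    distances: tuple[int, ...] = ENRICHMENT_DISTANCES,
    classes: list[str] | None = None,
    class_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Fisher's exact enrichment of outlier pairs among nearby regions.

    All ordered same-chromosome region pairs with midpoint distance
    within each cutoff are tabulated by the outlier status of the two
    members; two-sided Fisher p and the sample odds ratio are reported
    per distance, plus the fraction of outlier regions with a second
    outlier within the distance.  ``class_pair`` optionally restricts
    pairs, e.g. ``('promoter', 'active_enhancer')``.
    """
    status = np.asarray(is_outlier, dtype=bool)
    if len(status) != len(peaks):
        raise ValueError("outlier status length must match number of regions")
    mids = np.array([r.midpoint for r in peaks])
    chroms = np.array([r.chrom for r in peaks])
    klass = np.array(classes) if classes is not None else None

    rows = []
    for d in distances:
        n11 = n10 = n01 = n00 = 0
        outlier_with_partner: set[int] = set()
        for chrom in np.unique(chroms):
            sel = np.where(chroms == chrom)[0]
            order = sel[np.argsort(mids[sel])]
            m = mids[order]
            # two-pointer over sorted midpoints
            lo = 0
            for a in range(len(order)):
                while m[a] - m[lo] > d:
                    lo += 1
                for b in range(lo, a):
                    ia, ib = order[a], order[b]
                    for i, j in ((ia, ib), (ib, ia)):  # ordered pairs
                        if class_pair is not None:
                            if klass[i] != class_pair[0] or klass[j] != class_pair[1]:
                                continue
                        si, sj = status[i], status[j]
                        if si and sj:
                            n11 += 1
                            outlier_with_partner.add(i)
                        elif si and not sj:
                            n10 += 1
                        elif sj and not si:
                            n01 += 1
                        else:
                            n00 += 1
        table = np.array([[n11, n10], [n01, n00]])
        if table.sum() == 0:
            rows.append(
                {"distance": d, "odds_ratio": np.nan, "pvalue": np.nan,
                 "fraction_second_outlier": np.nan, "n_pairs": 0, "corrected": False}
            )
            continue
        _, p = stats.fisher_exact(table, alternative="two-sided")
        corrected = False
        if (table == 0).any():
            t = table + 0.5  # Haldane-Anscombe
            odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
            corrected = True
        else:
            odds = (n11 * n00) / (n10 * n01)
        n_out = int(status.sum())
        if class_pair is not None:
            n_out = int((status & (klass == class_pair[0])).sum()) if klass is not None else n_out
        frac = len([i for i in outlier_with_partner]) / n_out if n_out else np.nan
        rows.append(
            {"distance": d, "odds_ratio": float(odds), "pvalue": float(p),
             "fraction_second_outlier": frac, "n_pairs": int(table.sum()),
             "corrected": corrected}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hi-C contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Sparse symmetric binned contact scores."""

    bin_size: int = DEFAULT_BIN_SIZE
    contacts: dict[tuple[str, int, int], float] = field(default_factory=dict)

    def set(self, chrom: str, b1: int, b2: int, score: float) -> None:
        if score < 0:
            raise ValueError("contact scores must be >= 0")
        key = (chrom, min(b1, b2), max(b1, b2))
        self.contacts[key] = float(score)

    def get(self, chrom: str, b1: int, b2: int) -> float:
        return self.contacts.get((chrom, min(b1, b2), max(b1, b2)), 0.0)

    def bin_of(self, region: GenomicRegion) -> int:
        return region.midpoint // self.bin_size

    @classmethod
    def from_pairs(cls, df: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE) -> "ContactMap":
        """Build from a BEDPE-like table
        (chrom1,start1,end1,chrom2,start2,end2,score); inter-chromosomal
        rows are ignored."""
        cm = cls(bin_size=bin_size)
        for row in df.itertuples(index=False):
            c1, s1, e1, c2, s2, e2, score = row[:7]
            if c1 != c2:
                continue
            b1 = (int(s1) + int(e1)) // 2 // bin_size
            b2 = (int(s2) + int(e2)) // 2 // bin_size
            cm.set(str(c1), b1, b2, float(score))
        return cm

    @classmethod
    def from_tsv(cls, path: str, bin_size: int = DEFAULT_BIN_SIZE) -> "ContactMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls.from_pairs(df, bin_size=bin_size)


def hic_contact(
    source: GenomicRegion, target: GenomicRegion, contacts: ContactMap
) -> float:
    """Max contact score over the 3x3 neighborhood of the midpoint bins."""
    if source.chrom != target.chrom:
        return 0.0
    bs = contacts.bin_of(source)
    bt = contacts.bin_of(target)
    best = 0.0
    for i in (bs - 1, bs, bs + 1):
        if i < 0:
            continue
        for j in (bt - 1, bt, bt + 1):
            if j < 0:
                continue
            best = max(best, contacts.get(source.chrom, i, j))
    return best


def distance_power_regression(
    pairs: pd.DataFrame, log_offset: float = 1.0
) -> pd.DataFrame:
    """OLS of ``ln(contact + offset)`` on ``ln(distance)`` and the pair's
    outlier indicator; returns coefficients, SEs, t and p per term.

    ``pairs`` needs columns ``contact``, ``distance`` (> 0) and
    ``outlier_pair`` (bool/int).
    """
    d = pairs["distance"].to_numpy(dtype=np.float64)
    c = pairs["contact"].to_numpy(dtype=np.float64)
    o = pairs["outlier_pair"].to_numpy(dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("distances must be > 0")
    if np.any(c < 0):
        raise ValueError("contacts must be >= 0")
    X = sm.add_constant(np.column_stack([np.log(d), o]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate regression design")
    fit = sm.OLS(np.log(c + log_offset), X).fit()
    return pd.DataFrame(
        {
            "term": ["intercept", "log_distance", "outlier_pair"],
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "pvalue": fit.pvalues,
        }
    )


def approximate_contacts(
    distance: float | np.ndarray,
    intercept: float,
    slope: float,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> np.ndarray:
    """Power-law contact prediction ``exp(intercept) * d ** slope``;
    zero distances are clamped to one bin."""
    d = np.maximum(np.asarray(distance, dtype=np.float64), bin_size)
    return np.exp(intercept) * d**slope


# ---------------------------------------------------------------------------
# ABC scores
# ---------------------------------------------------------------------------

@dataclass
class AbcScore:
    source: str
    target: str
    contact: float
    score: float


def abc_scores(
    source: GenomicRegion,
    targets: list[GenomicRegion],
    contacts: ContactMap,
    accessibility: dict[str, float],
    vicinity: int = DEFAULT_VICINITY,
) -> list[AbcScore]:
    """Activity-by-contact scores from a source to its candidate targets.

    ``accessibility`` maps region name to total accessibility (sum of
    counts over samples).  Only targets within ``vicinity`` of the source
    midpoint enter the normalization; scores sum to 1 when the
    denominator is positive.  A zero denominator yields an empty list
    with a warning.
    """
    in_vicinity = [
        t
        for t in targets
        if t.chrom == source.chrom and abs(t.midpoint - source.midpoint) <= vicinity
    ]
    weights = []
    for t in in_vicinity:
        h = hic_contact(source, t, contacts)
        weights.append(h * accessibility.get(t.name, 0.0))
    denom = float(np.sum(weights))
    if denom <= 0:
        warnings.warn(
            f"zero ABC denominator for source {source.name}; scores undefined",
            UserWarning,
        )
        return []
    return [
        AbcScore(
            source=source.name,
            target=t.name,
            contact=hic_contact(source, t, contacts),
            score=w / denom,
        )
        for t, w in zip(in_vicinity, weights)
    ]


def abc_table(scores: list[AbcScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [s.source for s in scores],
            "target": [s.target for s in scores],
            "contact": [s.contact for s in scores],
            "abc": [s.score for s in scores],
        }
    )
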