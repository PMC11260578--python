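"""Link accessibility outliers to gene expression outliers.

Builds the per-(gene, sample) feature table consumed by any downstream
ranking model: promoter fold change / p-value / outlier status, maximum
absolute fold change over proximal outliers and over any outlier within
a window of the gene, and the ABC-weighted distal enhancer score
``sum_e |ABC_promoter->e * l2fc_e|``.  The boosted combined model itself
is an external estimator; its score column can be evaluated here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneModel, RegionAnnotation
from .metrics import auprc, pr_curve
from .outlier import OutlierResult
from .regions import PeakSet

RANKINGS = ("promoter", "proximal", "window", "distal", "combined")


def label_expression_outliers(
    result: OutlierResult, min_l2fc: float = 0.3, alpha: float = 0.05
) -> np.ndarray:
    """Expression-outlier labels: |l2fc| > min_l2fc AND padj < alpha
    (both strict)."""
    return (np.abs(result.l2fc) > min_l2fc) & (result.padj < alpha)


def build_gene_features(
    result: OutlierResult,
    peaks: PeakSet,
    annotations: list[RegionAnnotation],
    genes: GeneModel,
    abc: pd.DataFrame | None = None,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-(gene, sample) feature rows.

    ``abc`` maps promoter-to-enhancer ABC scores with columns
    ``gene_id``, ``region`` (enhancer region id) and ``abc``; when a gene
    has no promoter region its promoter features are missing (NaN) but
    the rows are retained.
    """
    if len(annotations) != len(peaks):
        raise ValueError("annotations length must match number of regions")
    region_index = {r.name: j for j, r in enumerate(peaks)}
    n_samples = result.l2fc.shape[0]
    sample_ids = (
        result.counts.sample_ids if result.counts is not None else list(range(n_samples))
    )

    promoter_regions: dict[str, list[int]] = {}
    proximal_regions: dict[str, list[int]] = {}
    for ann, region in zip(annotations, peaks):
        j = region_index[ann.region_id]
        if ann.klass == "promoter":
            for g in ann.linked_genes:
                promoter_regions.setdefault(g, []).append(j)
        elif ann.locality == "proximal":
            for g in ann.linked_genes:
                proximal_regions.setdefault(g, []).append(j)

    distal_terms: dict[str, list[tuple[int, float]]] = {}
    if abc is not None:
        for row in abc.itertuples(index=False):
            j = region_index.get(row.region)
            if j is not None:
                distal_terms.setdefault(str(row.gene_id), []).append((j, float(row.abc)))

    mids = np.array([r.midpoint for r in peaks])
    chroms = np.array([r.chrom for r in peaks])

    rows = []
    for gene in genes.genes:
        near = np.where((chroms == gene.chrom) & (np.abs(mids - gene.tss) <= window))[0]
        prom = promoter_regions.get(gene.gene_id, [])
        prox = proximal_regions.get(gene.gene_id, [])
        terms = distal_terms.get(gene.gene_id, [])
        for i in range(n_samples):
            if prom:
                # several promoters: min p, max |l2fc|
                p = float(np.min(result.pvalue[i, prom]))
                jbest = prom[int(np.argmax(np.abs(result.l2fc[i, prom])))]
                l2fc = float(result.l2fc[i, jbest])
                is_out = bool(result.is_outlier[i, prom].any())
            else:
                p, l2fc, is_out = np.nan, np.nan, False
            prox_out = [j for j in prox if result.is_outlier[i, j]]
            prox_feat = (
                float(np.max(np.abs(result.l2fc[i, prox_out]))) if prox_out else 0.0
            )
            win_out = [j for j in near if result.is_outlier[i, j]]
            win_feat = (
                float(np.max(np.abs(result.l2fc[i, win_out]))) if win_out else 0.0
            )
            distal = float(
                sum(abs(a * result.l2fc[i, j]) for j, a in terms)
            )
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "sample": sample_ids[i],
                    "promoter_l2fc": l2fc,
                    "promoter_p": p,
                    "promoter_is_outlier": is_out,
                    "proximal_max_abs_l2fc": prox_feat,
                    "window_max_abs_l2fc": win_feat,
                    "distal_abc_weighted": distal,
                }
            )
    return pd.DataFrame(rows)


_FEATURE_COLUMNS = {
    "promoter": "promoter_l2fc",
    "proximal": "proximal_max_abs_l2fc",
    "window": "window_max_abs_l2fc",
    "distal": "distal_abc_weighted",
    "combined": "combined_score",
}


def rank_and_evaluate(
    features: pd.DataFrame, labels: np.ndarray | pd.Series, ranking: str = "promoter"
) -> dict:
    """auPRC of ranking (gene, sample) rows by the chosen feature.

    ``combined`` expects an externally produced ``combined_score``
    column.  Promoter ranking uses |l2fc|; missing values score 0.
    """
    if ranking not in _FEATURE_COLUMNS:
        raise ValueError(f"ranking must be one of {RANKINGS}")
    col = _FEATURE_COLUMNS[ranking]
    if col not in features.columns:
        raise ValueError(f"feature column {col!r} missing from table")
    y = np.asarray(labels, dtype=bool)
    if not y.any():
        raise ValueError("no positive labels")
    score = features[col].to_numpy(dtype=np.float64)
    if ranking == "promoter":
        score = np.abs(score)
    score = np.nan_to_num(score, nan=0.0)
    precision, recall, _ = pr_curve(y, score)
    return {
        "auprc": auprc(y, score),
        "precision": precision,
        "recall": recall,
        "ranking": ranking,
    }
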