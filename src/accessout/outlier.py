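"""Negative-binomial linear-autoencoder outlier detection.

The model: counts are size-factor normalized, log-transformed and
centered; a PCA encoder projects them to a bottleneck that is
concatenated with known confounders; a linear decoder, initialized by
least squares and refined under the negative-binomial likelihood,
reconstructs per-(sample, region) expected counts; a two-sided NB test
with per-region MLE dispersion flags outliers.  Exactly one alternating
step is performed: initial dispersion fit, NB decoder fit, dispersion
refit.

The NB is parameterized by mean ``mu`` and size ``r`` with variance
``mu + mu**2 / r`` (large ``r`` approaches Poisson).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .normalization import (
    EXPECTED_FLOOR,
    NormalizedMatrix,
    back_transform,
    log_normalize,
    size_factors,
)
from .regions import CountMatrix

DISPERSION_BOUNDS = (0.01, 1000.0)


# ---------------------------------------------------------------------------
# negative binomial primitives
# ---------------------------------------------------------------------------

def nb_logpmf(k: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Log pmf of NB(mean=mu, size=r); fully vectorized."""
    k = np.asarray(k, dtype=np.float64)
    mu = np.maximum(np.asarray(mu, dtype=np.float64), EXPECTED_FLOOR)
    r = np.asarray(r, dtype=np.float64)
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mu))
        + k * np.log(mu / (r + mu))
    )


def _nb_cdf(k, mu, r):
    mu = np.maximum(mu, EXPECTED_FLOOR)
    return stats.nbinom.cdf(k, r, r / (r + mu))


def _nb_sf_exclusive(k, mu, r):
    """P(X >= k) = 1 - F(k - 1)."""
    mu = np.maximum(mu, EXPECTED_FLOOR)
    return stats.nbinom.sf(k - 1, r, r / (r + mu))


# ---------------------------------------------------------------------------
# confounder design
# ---------------------------------------------------------------------------

@dataclass
class ConfounderDesign:
    """Known-confounder design matrix.

    Categorical columns are one-hot encoded with the first level dropped,
    numeric columns are z-scored, and a constant column is always
    appended.  Raises on rank deficiency, naming the collinear columns.
    """

    matrix: np.ndarray
    names: list[str]

    @classmethod
    def from_table(
        cls, table: pd.DataFrame | None, n_samples: int | None = None
    ) -> "ConfounderDesign":
        if table is None:
            if n_samples is None:
                raise ValueError("n_samples required when table is None")
            return cls(matrix=np.ones((n_samples, 1)), names=["const"])
        cols: list[np.ndarray] = []
        names: list[str] = []
        for col in table.columns:
            s = table[col]
            if pd.api.types.is_numeric_dtype(s):
                v = s.to_numpy(dtype=np.float64)
                sd = v.std()
                if sd == 0:
                    warnings.warn(
                        f"constant numeric confounder {col!r} dropped", UserWarning
                    )
                    continue
                cols.append((v - v.mean()) / sd)
                names.append(str(col))
            else:
                dummies = pd.get_dummies(s.astype("category"), drop_first=True)
                for dcol in dummies.columns:
                    cols.append(dummies[dcol].to_numpy(dtype=np.float64))
                    names.append(f"{col}={dcol}")
        cols.append(np.ones(len(table)))
        names.append("const")
        m = np.column_stack(cols)
        rank = np.linalg.matrix_rank(m)
        if rank < m.shape[1]:
            # identify columns that do not increase the rank incrementally
            bad = []
            r = 0
            for j in range(m.shape[1]):
                rj = np.linalg.matrix_rank(m[:, : j + 1])
                if rj == r:
                    bad.append(names[j])
                r = rj
            raise ValueError(f"confounder design is rank-deficient; collinear: {bad}")
        return cls(matrix=m, names=names)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# model state / results
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    encoder_weights: np.ndarray  # regions x q
    decoder_weights: np.ndarray  # (q + c) x regions
    bottleneck: int
    dispersions: np.ndarray  # per region, within DISPERSION_BOUNDS
    confounders: ConfounderDesign | None = None
    size_factors: np.ndarray | None = None
    region_log_means: np.ndarray | None = None


@dataclass
class OutlierResult:
    expected: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray
    l2fc: np.ndarray
    zscore: np.ndarray
    is_outlier: np.ndarray
    corrected: np.ndarray
    counts: CountMatrix | None = None
    dispersions: np.ndarray | None = None
    size_factors_: np.ndarray | None = None

    def to_anndata(self):
        import anndata as ad

        cm = self.counts
        adata = ad.AnnData(
            X=cm.counts.astype(np.float64) if cm is not None else self.expected,
            layers={
                "expected": self.expected,
                "pvalue": self.pvalue,
                "padj": self.padj,
                "l2fc": self.l2fc,
                "zscore": self.zscore,
                "is_outlier": self.is_outlier.astype(np.int8),
                "corrected": self.corrected,
            },
        )
        if cm is not None:
            adata.obs_names = cm.sample_ids
            adata.var = cm.regions.to_frame()
        if self.size_factors_ is not None:
            adata.obs["size_factor"] = self.size_factors_
        if self.dispersions is not None:
            adata.var["dispersion"] = self.dispersions
        return adata

    def outlier_table(self) -> pd.DataFrame:
        """Flat table of called outliers."""
        cm = self.counts
        rows, cols = np.nonzero(self.is_outlier)
        return pd.DataFrame(
            {
                "sample": [cm.sample_ids[i] for i in rows] if cm else rows,
                "region": [cm.regions.names[j] for j in cols] if cm else cols,
                "direction": np.where(self.l2fc[rows, cols] > 0, "over", "under"),
                "pvalue": self.pvalue[rows, cols],
                "padj": self.padj[rows, cols],
                "l2fc": self.l2fc[rows, cols],
                "zscore": self.zscore[rows, cols],
                "count": cm.counts[rows, cols] if cm else np.nan,
                "expected": self.expected[rows, cols],
            }
        )


def result_from_anndata(adata) -> OutlierResult:
    cm = CountMatrix.from_anndata(adata)
    return OutlierResult(
        expected=np.asarray(adata.layers["expected"]),
        pvalue=np.asarray(adata.layers["pvalue"]),
        padj=np.asarray(adata.layers["padj"]),
        l2fc=np.asarray(adata.layers["l2fc"]),
        zscore=np.asarray(adata.layers["zscore"]),
        is_outlier=np.asarray(adata.layers["is_outlier"]).astype(bool),
        corrected=np.asarray(adata.layers["corrected"]),
        counts=cm,
        dispersions=(
            adata.var["dispersion"].to_numpy() if "dispersion" in adata.var else None
        ),
        size_factors_=(
            adata.obs["size_factor"].to_numpy() if "size_factor" in adata.obs else None
        ),
    )


# ---------------------------------------------------------------------------
# encoder / decoder
# ---------------------------------------------------------------------------

def fit_encoder(x: NormalizedMatrix | np.ndarray, q: int) -> np.ndarray:
    """PCA rotation: columns are the top-q right singular vectors of x.

    The encoder is never trained further.
    """
    xm = x.x if isinstance(x, NormalizedMatrix) else np.asarray(x)
    n, p = xm.shape
    if not (1 <= q < min(n, p)):
        raise ValueError(f"bottleneck q={q} must satisfy 1 <= q < min(n, p)={min(n, p)}")
    _, _, vt = np.linalg.svd(xm, full_matrices=False)
    return vt[:q].T


def build_latent(
    x: NormalizedMatrix | np.ndarray,
    encoder_weights: np.ndarray,
    confounders: ConfounderDesign | None = None,
) -> np.ndarray:
    """Latent representation ``H = [x We | c_known]``."""
    xm = x.x if isinstance(x, NormalizedMatrix) else np.asarray(x)
    h = xm @ encoder_weights
    if confounders is None:
        return h
    if confounders.matrix.shape[0] != xm.shape[0]:
        raise ValueError("confounder rows do not match sample count")
    return np.concatenate([h, confounders.matrix], axis=1)


def init_decoder(h: np.ndarray, x: NormalizedMatrix | np.ndarray) -> np.ndarray:
    """Least-squares decoder initialization, one column per region."""
    xm = x.x if isinstance(x, NormalizedMatrix) else np.asarray(x)
    if np.linalg.matrix_rank(h) < h.shape[1]:
        warnings.warn(
            "latent matrix is rank-deficient; using pseudoinverse", UserWarning
        )
        return np.linalg.pinv(h) @ xm
    w, *_ = np.linalg.lstsq(h, xm, rcond=None)
    return w


# ---------------------------------------------------------------------------
# dispersion MLE
# ---------------------------------------------------------------------------

def fit_dispersion(
    counts: np.ndarray,
    expected: np.ndarray,
    bounds: tuple[float, float] = DISPERSION_BOUNDS,
) -> np.ndarray:
    """Per-region bounded MLE of the NB dispersion.

    Each region is an independent 1-d problem in log-dispersion; a coarse
    vectorized log-grid brackets the optimum, then a bounded scalar
    optimizer refines it.  The returned values always lie in ``bounds``.
    """
    k = np.asarray(counts, dtype=np.float64)
    mu = np.maximum(np.asarray(expected, dtype=np.float64), EXPECTED_FLOOR)
    if k.ndim == 1:
        k = k[None, :]
        mu = mu[None, :]
    lo, hi = bounds
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), 41))
    # log-likelihood per (grid point, region), vectorized over samples
    ll = np.empty((grid.size, k.shape[1]))
    for g, r in enumerate(grid):
        ll[g] = nb_logpmf(k, mu, r).sum(axis=0)
    if not np.all(np.isfinite(ll)):
        bad = np.where(~np.isfinite(ll).all(axis=0))[0]
        raise FloatingPointError(
            f"non-finite NB likelihood for region index {bad[0]}"
        )
    best = ll.argmax(axis=0)

    out = np.empty(k.shape[1])
    log_grid = np.log(grid)
    for j in range(k.shape[1]):
        b = best[j]
        a = log_grid[max(b - 1, 0)]
        c = log_grid[min(b + 1, grid.size - 1)]
        kj, muj = k[:, j], mu[:, j]

        def neg(t: float) -> float:
            return -nb_logpmf(kj, muj, np.exp(t)).sum()

        if a == c:
            out[j] = grid[b]
            continue
        res = optimize.minimize_scalar(
            neg, bounds=(a, c), method="bounded", options={"xatol": 1e-10}
        )
        best_r = float(np.clip(np.exp(res.x), lo, hi))
        # the bounded solver stops short of the interval ends; snap to a
        # bound whenever it is at least as likely
        for edge in (lo, hi):
            if neg(np.log(edge)) <= -nb_logpmf(kj, muj, best_r).sum():
                best_r = edge
        out[j] = best_r
    return out


# ---------------------------------------------------------------------------
# NB decoder fit
# ---------------------------------------------------------------------------

def _expected_from_decoder(h, w, region_log_means, sf):
    xhat = h @ w
    return back_transform(xhat, region_log_means, sf)


def nb_loglik_per_region(k, mu, r) -> np.ndarray:
    return nb_logpmf(k, mu, np.asarray(r)[None, :]).sum(axis=0)


def fit_decoder(
    h: np.ndarray,
    counts: np.ndarray,
    dispersions: np.ndarray,
    sf: np.ndarray,
    region_log_means: np.ndarray,
    w_init: np.ndarray | None = None,
    maxiter: int = 200,
    gtol: float = 1e-6,
) -> np.ndarray:
    """Maximize the NB likelihood over decoder weights, all regions jointly.

    The objective is separable across regions, so a single L-BFGS-B run
    over the flattened weight matrix solves every per-region problem at
    once.  Regions whose likelihood would fall below the least-squares
    initialization keep their initial weights.
    """
    k = np.asarray(counts, dtype=np.float64)
    r = np.asarray(dispersions, dtype=np.float64)
    if w_init is None:
        raise ValueError("w_init (least-squares decoder) is required")
    shape = w_init.shape

    def objective(flat: np.ndarray):
        w = flat.reshape(shape)
        eta = h @ w + region_log_means[None, :]
        raw = np.exp(eta) * sf[:, None] - 1.0
        floored = raw < EXPECTED_FLOOR
        mu = np.where(floored, EXPECTED_FLOOR, raw)
        ll = nb_logpmf(k, mu, r[None, :]).sum()
        # d(-ll)/dmu, zeroed where the floor is active
        dmu = -(k / mu - (k + r[None, :]) / (mu + r[None, :]))
        deta = np.where(floored, 0.0, dmu * np.exp(eta) * sf[:, None])
        grad = h.T @ deta
        return -ll, grad.ravel()

    res = optimize.minimize(
        objective,
        w_init.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    msg = str(res.message).upper()
    if not res.success and "ITERATIONS REACHED LIMIT" not in msg:
        warnings.warn(
            f"decoder optimization did not fully converge: {res.message}", UserWarning
        )
    w = res.x.reshape(shape)

    mu_new = _expected_from_decoder(h, w, region_log_means, sf)
    mu_old = _expected_from_decoder(h, w_init, region_log_means, sf)
    ll_new = nb_loglik_per_region(k, mu_new, r)
    ll_old = nb_loglik_per_region(k, mu_old, r)
    worse = ll_new < ll_old
    if worse.any():
        w = w.copy()
        w[:, worse] = w_init[:, worse]
    return w


# ---------------------------------------------------------------------------
# test, adjustment, effect sizes, calls
# ---------------------------------------------------------------------------

def nb_pvalues(
    counts: np.ndarray,
    expected: np.ndarray,
    dispersions: np.ndarray,
    doubled: bool = True,
) -> np.ndarray:
    """Two-sided NB test p-values.

    Default is the standard doubling ``2 * min(1/2, F(k), 1 - F(k-1))``;
    ``doubled=False`` gives the half-capped variant
    ``min(1/2, F(k), 1 - F(k-1))`` for comparison.
    """
    k = np.asarray(counts, dtype=np.float64)
    mu = np.asarray(expected, dtype=np.float64)
    r = np.asarray(dispersions, dtype=np.float64)
    if r.ndim == 1:
        r = r[None, :]
    lower = _nb_cdf(k, mu, r)
    upper = _nb_sf_exclusive(k, mu, r)
    core = np.minimum(0.5, np.minimum(lower, upper))
    p = 2.0 * core if doubled else core
    return np.clip(p, np.finfo(np.float64).tiny, 1.0)


def nb_logpvalues(
    counts: np.ndarray, expected: np.ndarray, dispersions: np.ndarray
) -> np.ndarray:
    """Natural-log two-sided NB p-values (doubled form).

    Keeps ranking resolution where the linear-scale p-value underflows.
    """
    k = np.asarray(counts, dtype=np.float64)
    mu = np.maximum(np.asarray(expected, dtype=np.float64), EXPECTED_FLOOR)
    r = np.asarray(dispersions, dtype=np.float64)
    if r.ndim == 1:
        r = r[None, :]
    p = r / (r + mu)
    logcdf = stats.nbinom.logcdf(k, r, p)
    logsf = stats.nbinom.logsf(k - 1, r, p)
    core = np.minimum(np.log(0.5), np.minimum(logcdf, logsf))
    return np.minimum(np.log(2.0) + core, 0.0)


def outlier_score(pvalue: np.ndarray, zscore: np.ndarray) -> np.ndarray:
    """Dense ranking score: p ascending, ties broken by |Z| descending.

    Returns higher-is-more-outlier scores suitable for auPRC.
    """
    p = np.asarray(pvalue, dtype=np.float64).ravel()
    z = np.abs(np.asarray(zscore, dtype=np.float64)).ravel()
    order = np.lexsort((-z, p))  # primary: p asc; secondary: |z| desc
    score = np.empty_like(p)
    score[order] = -np.arange(p.size, dtype=np.float64)
    return score.reshape(np.asarray(pvalue).shape)


def adjust_pvalues(pvalues: np.ndarray, scope: str = "per_sample") -> np.ndarray:
    """Benjamini-Yekutieli adjustment.

    ``scope='per_sample'`` applies the step-up per sample across regions
    (the default); ``scope='global'`` adjusts the whole matrix at once.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if scope == "global":
        flat = multipletests(p.ravel(), method="fdr_by")[1]
        return flat.reshape(p.shape)
    if scope != "per_sample":
        raise ValueError("scope must be 'per_sample' or 'global'")
    out = np.empty_like(p)
    for i in range(p.shape[0]):
        out[i] = multipletests(p[i], method="fdr_by")[1]
    return out


def effect_sizes(
    counts: np.ndarray, expected: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log2 fold changes and their per-region Z-scores.

    ``l2fc = log2((k + 1) / (khat + 1))``; the Z-score standardizes l2fc
    within each region (mean 0, sd 1 across samples).
    """
    k = np.asarray(counts, dtype=np.float64)
    mu = np.asarray(expected, dtype=np.float64)
    l2fc = np.log2((k + 1.0) / (mu + 1.0))
    mean = l2fc.mean(axis=0)
    sd = l2fc.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} region(s) with zero fold-change variance; "
            "Z-scores set to 0",
            UserWarning,
        )
    sd_safe = np.where(zero, 1.0, sd)
    z = (l2fc - mean) / sd_safe
    z[:, zero] = 0.0
    return l2fc, z


def call_outliers(
    padj: np.ndarray,
    l2fc: np.ndarray,
    counts: np.ndarray,
    expected: np.ndarray,
    alpha: float = 0.05,
    min_l2fc: float = 0.5,
    min_count: float = 50,
) -> np.ndarray:
    """Flag (sample, region) entries: padj < alpha, |l2fc| > min_l2fc and
    observed or expected count >= min_count."""
    k = np.asarray(counts)
    mu = np.asarray(expected)
    return (
        (np.asarray(padj) < alpha)
        & (np.abs(np.asarray(l2fc)) > min_l2fc)
        & ((k >= min_count) | (mu >= min_count))
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _winsorize_columns(x: np.ndarray, n_sd: float = 4.0) -> np.ndarray:
    """Clip each column to median +/- n_sd robust standard deviations."""
    med = np.median(x, axis=0)
    sd = 1.4826 * np.median(np.abs(x - med), axis=0)  # MAD -> sigma
    sd = np.maximum(sd, 1e-3)
    return np.clip(x, med - n_sd * sd, med + n_sd * sd)


def _robust_clean(
    x: np.ndarray, design: np.ndarray, gross_sd: float = 8.0, resid_sd: float = 4.0
) -> np.ndarray:
    """Limit single-entry leverage on the model fit.

    An injected or artifactual entry tens of sigma out would otherwise
    hijack the PCA rotation and drag the NB decoder fit of its whole
    region (and mask itself in its own expectation).  Two stages: a
    marginal clip at ``gross_sd`` robust sd removes gross leverage, then
    entries are clipped at ``resid_sd`` robust sd around a
    known-confounder least-squares fit, so genuine confounder structure
    is never truncated.  Applied to the model *input* only — the NB test
    always uses raw counts.
    """
    x1 = _winsorize_columns(x, gross_sd)
    beta, *_ = np.linalg.lstsq(design, x1, rcond=None)
    fitted = design @ beta
    resid = x1 - fitted
    med = np.median(resid, axis=0)
    sd = np.maximum(1.4826 * np.median(np.abs(resid - med), axis=0), 1e-3)
    resid = np.clip(resid, med - resid_sd * sd, med + resid_sd * sd)
    return fitted + resid


def run_epiout(
    counts: CountMatrix | np.ndarray,
    confounders: pd.DataFrame | ConfounderDesign | None = None,
    q: int = 5,
    alpha: float = 0.05,
    min_l2fc: float = 0.5,
    min_count: float = 50,
    padj_scope: str = "per_sample",
    doubled_pvalues: bool = True,
    robust_input: bool = True,
) -> tuple[ModelState, OutlierResult]:
    """Full pipeline: normalize, encode, decode, test, adjust, call.

    One alternating optimization step is performed: dispersions are
    fitted on the least-squares expectation, the decoder is refined under
    the NB likelihood, and dispersions are re-estimated once.
    Deterministic given inputs.

    With ``robust_input`` (default) the model is *fitted* on
    leverage-clipped data (see :func:`_winsorize_columns`) so that a
    single extreme entry cannot hijack a region's expectation or
    dispersion; the NB test itself always uses the raw counts.
    """
    cm = counts if isinstance(counts, CountMatrix) else None
    k = counts.counts if cm is not None else np.asarray(counts)

    if isinstance(confounders, ConfounderDesign):
        design = confounders
    elif confounders is not None:
        design = ConfounderDesign.from_table(confounders)
    else:
        design = ConfounderDesign.from_table(None, n_samples=k.shape[0])

    sf = size_factors(k)
    norm = log_normalize(k, sf)
    if robust_input:
        x_fit = _robust_clean(norm.x, design.matrix)
        k_fit = np.rint(back_transform(x_fit, norm.region_log_means, sf))
    else:
        x_fit, k_fit = norm.x, k
    we = fit_encoder(x_fit, q)
    h = build_latent(x_fit, we, design)
    wd = init_decoder(h, x_fit)

    expected0 = _expected_from_decoder(h, wd, norm.region_log_means, sf)
    disp0 = fit_dispersion(k_fit, expected0)
    wd = fit_decoder(h, k_fit, disp0, sf, norm.region_log_means, w_init=wd)
    expected = _expected_from_decoder(h, wd, norm.region_log_means, sf)
    disp = fit_dispersion(k_fit, expected)

    pv = nb_pvalues(k, expected, disp, doubled=doubled_pvalues)
    padj = adjust_pvalues(pv, scope=padj_scope)
    l2fc, z = effect_sizes(k, expected)
    flags = call_outliers(
        padj, l2fc, k, expected, alpha=alpha, min_l2fc=min_l2fc, min_count=min_count
    )
    state = ModelState(
        encoder_weights=we,
        decoder_weights=wd,
        bottleneck=q,
        dispersions=disp,
        confounders=design,
        size_factors=sf,
        region_log_means=norm.region_log_means,
    )
    result = OutlierResult(
        expected=expected,
        pvalue=pv,
        padj=padj,
        l2fc=l2fc,
        zscore=z,
        is_outlier=flags,
        corrected=k - expected,
        counts=cm,
        dispersions=disp,
        size_factors_=sf,
    )
    return state, result


def tune_bottleneck(
    counts: CountMatrix | np.ndarray,
    confounders: pd.DataFrame | None,
    candidate_qs: list[int],
    seed: int = 0,
    p_inject: float = 5e-4,
) -> int:
    """Pick the bottleneck maximizing auPRC on one injected validation mask."""
    from .injection import inject, sample_mask
    from .metrics import auprc

    if len(candidate_qs) < 1:
        raise ValueError("at least one candidate bottleneck required")
    if len(candidate_qs) == 1:
        return candidate_qs[0]

    k = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    norm = log_normalize(k)
    mask = sample_mask(k.shape[0], k.shape[1], p_inject=p_inject, seed=seed)
    _, counts_inj = inject(norm, mask.mask, seed=seed + 1)

    best_q, best_score = candidate_qs[0], -np.inf
    for q in candidate_qs:
        _, res = run_epiout(counts_inj, confounders, q=q)
        score = auprc((mask.mask != 0).ravel(), -res.pvalue.ravel())
        if score > best_score:
            best_q, best_score = q, score
    return best_q


def sample_correlation(
    counts: np.ndarray, expected: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Pearson correlation between sample rows.

    With ``expected`` given, correlates corrected counts ``k - khat``;
    otherwise raw counts.  Constant rows yield NaN entries which are
    excluded from the mean off-diagonal summary.
    """
    k = np.asarray(counts, dtype=np.float64)
    if k.shape[0] < 2:
        raise ValueError("need at least two samples")
    mat = k - np.asarray(expected, dtype=np.float64) if expected is not None else k
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        warnings.warn("constant sample row(s); correlations reported as NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    off = ~np.eye(corr.shape[0], dtype=bool)
    vals = corr[off]
    mean_off = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return corr, mean_off
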