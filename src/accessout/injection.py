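"""Artificial outlier injection and the benchmark baselines.

Injection plants signed shifts on the centered log scale: an entry
selected by the mask is moved by ``sigma_j * exp(N(3, 1))`` in the mask's
direction, where ``sigma_j`` is the per-region standard deviation.
Shifted values are mapped back to integer counts and each method is
scored on how well it ranks the planted entries (auPRC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import auprc, precision_recall_at
from .normalization import NormalizedMatrix, back_transform, log_normalize
from .outlier import effect_sizes, fit_dispersion, fit_encoder, nb_pvalues
from .regions import CountMatrix

DEFAULT_P_INJECT = 5e-4
LOG_AMP_MEAN = 3.0
LOG_AMP_SD = 1.0


@dataclass
class InjectionMask:
    """Ternary mask: +1 over-accessibility, -1 under-accessibility, 0 none."""

    mask: np.ndarray
    p_inject: float
    seed: int

    def __post_init__(self) -> None:
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (-1, 0, 1))):
            raise ValueError("mask entries must be in {-1, 0, +1}")

    @property
    def n_injected(self) -> int:
        return int(np.count_nonzero(self.mask))


def sample_mask(
    n_samples: int,
    n_regions: int,
    p_inject: float = DEFAULT_P_INJECT,
    seed: int = 0,
) -> InjectionMask:
    """I.i.d. entries: +1 and -1 each with probability ``p_inject``."""
    if not 2 * p_inject < 1:
        raise ValueError("2 * p_inject must be < 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_samples, n_regions))
    mask = np.zeros((n_samples, n_regions), dtype=np.int8)
    mask[u < p_inject] = 1
    mask[(u >= p_inject) & (u < 2 * p_inject)] = -1
    return InjectionMask(mask=mask, p_inject=p_inject, seed=seed)


def inject(
    norm: NormalizedMatrix,
    mask: np.ndarray,
    log_amp_mean: float = LOG_AMP_MEAN,
    log_amp_sd: float = LOG_AMP_SD,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the mask on the log scale and return (x_inj, integer counts).

    Counts are recovered with the inverse transform and rounded to the
    nearest non-negative integer; unmasked entries round-trip to the
    original counts.
    """
    if mask.shape != norm.x.shape:
        raise ValueError("mask shape does not match matrix")
    rng = np.random.default_rng(seed)
    amplitude = np.exp(rng.normal(log_amp_mean, log_amp_sd, size=norm.x.shape))
    sigma = norm.region_sd()
    x_inj = norm.x + sigma[None, :] * amplitude * mask
    raw = back_transform(x_inj, norm.region_log_means, norm.size_factors)
    # extreme amplitudes can overflow exp(); cap well below int64 range
    counts_inj = np.clip(np.rint(raw), 0, 1e15).astype(np.int64)
    return x_inj, counts_inj


def naive_nb_baseline(counts_inj: np.ndarray) -> np.ndarray:
    """NB test with a non-sample-specific mean: per-region sample average."""
    k = np.asarray(counts_inj, dtype=np.float64)
    expected = np.broadcast_to(k.mean(axis=0), k.shape)
    disp = fit_dispersion(k, expected)
    return nb_pvalues(k, expected, disp)


def pca_baseline(counts_inj: np.ndarray, q: int) -> np.ndarray:
    """|Z| scores from a plain PCA reconstruction (no NB test)."""
    norm = log_normalize(np.asarray(counts_inj))
    we = fit_encoder(norm, q)
    xhat = (norm.x @ we) @ we.T
    expected = back_transform(xhat, norm.region_log_means, norm.size_factors)
    _, z = effect_sizes(counts_inj, expected)
    return np.abs(z)


def evaluate_auprc(
    scores: np.ndarray | list[np.ndarray],
    masks: np.ndarray | list[np.ndarray],
    flags: np.ndarray | list[np.ndarray] | None = None,
) -> dict:
    """auPRC of recovering mask != 0, over one or several repetitions.

    ``scores`` are outlier-ness scores (higher = more outlier-like; pass
    ``-p`` for p-values).  Repetitions whose mask has no positives are
    skipped with a warning.  ``flags`` optionally supplies hard calls
    (e.g. padj < 0.05 or |Z| > 2) for fixed-cutoff precision/recall.
    """
    if isinstance(scores, np.ndarray):
        scores = [scores]
    if isinstance(masks, np.ndarray):
        masks = [masks]
    if flags is not None and isinstance(flags, np.ndarray):
        flags = [flags]
    if len(scores) != len(masks):
        raise ValueError("scores and masks repetition counts differ")

    values = []
    cutoffs = []
    for i, (s, m) in enumerate(zip(scores, masks)):
        truth = np.asarray(m) != 0
        if not truth.any():
            warnings.warn(f"mask {i} has zero positives; repetition skipped")
            continue
        values.append(auprc(truth, s))
        if flags is not None:
            cutoffs.append(precision_recall_at(flags[i], truth))
    out = {
        "auprc_mean": float(np.mean(values)) if values else float("nan"),
        "auprc_sd": float(np.std(values)) if values else float("nan"),
        "auprc_values": values,
        "n_repetitions": len(values),
    }
    if cutoffs:
        out["cutoff_precision_mean"] = float(np.mean([c[0] for c in cutoffs]))
        out["cutoff_recall_mean"] = float(np.mean([c[1] for c in cutoffs]))
    return out


def run_benchmark(
    counts: CountMatrix | np.ndarray,
    confounders=None,
    methods: tuple[str, ...] = ("epiout", "pca", "naive"),
    q: int = 5,
    n_masks: int = 10,
    p_inject: float = DEFAULT_P_INJECT,
    seed: int = 0,
) -> dict[str, dict]:
    """Inject ``n_masks`` independent masks and score each method.

    Test masks use derived seeds ``seed + 1 .. seed + n_masks`` (seed
    itself is reserved for the validation mask used by bottleneck
    tuning).  Returns per-method summaries from :func:`evaluate_auprc`.
    """
    from .outlier import nb_logpvalues, outlier_score, run_epiout

    k = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    norm = log_normalize(k)

    per_method: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    mask_list: list[np.ndarray] = []
    for rep in range(1, n_masks + 1):
        m = sample_mask(k.shape[0], k.shape[1], p_inject=p_inject, seed=seed + rep)
        _, counts_inj = inject(norm, m.mask, seed=seed + rep)
        mask_list.append(m.mask)
        for method in methods:
            if method == "epiout":
                _, res = run_epiout(counts_inj, confounders, q=q)
                # log-scale p keeps resolution below float underflow;
                # residual ties broken by |Z|
                logp = nb_logpvalues(counts_inj, res.expected, res.dispersions)
                per_method[method].append(outlier_score(logp, res.zscore))
            elif method == "pca":
                per_method[method].append(pca_baseline(counts_inj, q))
            elif method == "naive":
                per_method[method].append(-naive_nb_baseline(counts_inj))
            else:
                raise ValueError(f"unknown method {method!r}")
    return {
        method: evaluate_auprc(score_list, mask_list)
        for method, score_list in per_method.items()
    }
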