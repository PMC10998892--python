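"""Evaluation metrics for predicted connectomes.

Six metrics score a predicted post-surgery network against the ground truth:
MSE, MAE, Pearson correlation (PCC) and cosine similarity (CS) on the
flattened log-scale edge vectors, plus Kullback-Leibler and Jensen-Shannon
divergences between the weight probability distributions of the two graphs.
KL/JS use base-2 logarithms so that JS is bounded by 1 and interpretable as a
distance.  The module also provides the cross-validation diagnostics: fold
z-scores, the Grubbs single-outlier test, and a Q-Q normality correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .assembly import Connectome

__all__ = [
    "EvalMetrics",
    "WeightDistribution",
    "reconstruction_metrics",
    "weight_distribution",
    "kl_divergence",
    "js_divergence",
    "fold_zscores",
    "grubbs_test",
    "qq_normality",
]


@dataclass(frozen=True)
class EvalMetrics:
    mse: float
    mae: float
    pcc: float
    cs: float
    kl: float = math.nan
    js: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "pcc": self.pcc,
            "cs": self.cs,
            "kl": self.kl,
            "js": self.js,
        }


@dataclass(frozen=True)
class WeightDistribution:
    """Smoothed probability histogram of positive log-weights."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if probs.size != edges.size - 1:
            raise ValueError("probabilities must have one entry per bin")
        if np.any(probs < 0) or not math.isclose(float(probs.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("probabilities must be non-negative and sum to 1")

    def _check_binning(self, other: "WeightDistribution") -> None:
        if self.bin_edges.shape != other.bin_edges.shape or not np.allclose(
            self.bin_edges, other.bin_edges
        ):
            raise ValueError("distributions use different binnings")


def reconstruction_metrics(pred: np.ndarray, truth: np.ndarray) -> EvalMetrics:
    """MSE, MAE, PCC and cosine similarity on flattened edge vectors."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.shape != t.shape or p.size < 2:
        raise ValueError("pred and truth must be equal-length vectors (>= 2)")
    diff = p - t
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    if t.std() == 0 or p.std() == 0:
        pcc = math.nan  # undefined for a constant vector
    else:
        pcc = float(np.corrcoef(p, t)[0, 1])
    denom = float(np.linalg.norm(p) * np.linalg.norm(t))
    cs = float(np.dot(p, t) / denom) if denom > 0 else math.nan
    return EvalMetrics(mse=mse, mae=mae, pcc=pcc, cs=cs)


def weight_distribution(
    source: Connectome | np.ndarray,
    n_bins: int = 50,
    epsilon: float = 1e-10,
    bin_range: tuple[float, float] | None = None,
) -> WeightDistribution:
    """Probability histogram of the positive log-weights of a graph.

    ``bin_range`` should be the pooled range of the pair being compared so
    that two distributions share a binning; empty bins are epsilon-smoothed
    and the histogram renormalized.
    """
    if isinstance(source, Connectome):
        if not source.log_scale:
            raise ValueError("weight distributions are defined on the log scale")
        iu = np.triu_indices(len(source.node_labels), k=1)
        values = source.weights[iu]
    else:
        values = np.asarray(source, dtype=float).ravel()
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("no positive edges: degenerate weight distribution")
    lo, hi = bin_range if bin_range is not None else (float(values.min()), float(values.max()))
    if hi <= lo:
        hi = lo + 1e-9
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    probs = counts.astype(float) + epsilon
    probs /= probs.sum()
    return WeightDistribution(bin_edges=edges, probabilities=probs, epsilon=epsilon)


def kl_divergence(p: WeightDistribution, q: WeightDistribution) -> float:
    """Kullback-Leibler divergence sum p log2(p/q); asymmetric, >= 0."""
    p._check_binning(q)
    return float(np.sum(p.probabilities * np.log2(p.probabilities / q.probabilities)))


def js_divergence(p: WeightDistribution, q: WeightDistribution) -> float:
    """Jensen-Shannon divergence with base-2 logs: symmetric, in [0, 1]."""
    p._check_binning(q)
    m = WeightDistribution(
        bin_edges=p.bin_edges,
        probabilities=0.5 * (p.probabilities + q.probabilities),
        epsilon=p.epsilon,
    )
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def fold_zscores(metric_values: Sequence[float]) -> np.ndarray:
    """Standardize per-fold metric values (sample standard deviation)."""
    x = np.asarray(metric_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 folds to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scores undefined")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class GrubbsResult:
    is_outlier: bool
    g_statistic: float
    critical_value: float
    index: int


def grubbs_test(
    values: Sequence[float], alpha: float = 0.05, two_tailed: bool = True
) -> GrubbsResult:
    """Grubbs single-outlier test.

    G = max |x - mean| / sd is compared with the Student-t based critical
    value at significance ``alpha``; a zero-variance sample yields a
    no-outlier result.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(False, 0.0, math.inf, 0)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    tail_p = alpha / (2 * n) if two_tailed else alpha / n
    t_crit = stats.t.ppf(1 - tail_p, n - 2)
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    return GrubbsResult(is_outlier=g > crit, g_statistic=g, critical_value=float(crit), index=idx)


def qq_normality(zscores: Sequence[float]) -> tuple[float, float]:
    """Correlation between observed and theoretical normal quantiles.

    Sorted values are paired with standard-normal quantiles at plotting
    positions (i - 0.5)/n; returns the Pearson r and its two-tailed p-value.
    """
    x = np.sort(np.asarray(zscores, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 values for a Q-Q check")
    if x.std() == 0:
        raise ValueError("ties-only input: Q-Q correlation undefined")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r, p = stats.pearsonr(theo, x)
    return float(r), float(p)
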