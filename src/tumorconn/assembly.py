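"""Structural connectome containers and the lesion-merge arithmetic.

The tractography stages themselves (FOD estimation, probabilistic tracking,
streamline filtering) are upstream external tools; this module implements the
connectome-level arithmetic that combines their numeric outputs:

* the lesion streamline budget — the average number of streamlines crossing
  the lesion in a healthy cohort, which sets how many streamlines are seeded
  inside the lesion;
* the greedy merge of the healthy and lesion connectivity matrices,
  omega_ij = max(omega_ij_healthy, omega_ij_lesion);
* log(1 + w) weight normalization (and its inverse) used before any learning;
* weighted degree distributions and a maximum-likelihood power-law tail fit
  used as a scale-free diagnostic of reconstructed networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

Voxel = tuple[int, int, int]

__all__ = [
    "Connectome",
    "LesionBudget",
    "PowerLawFit",
    "intersect_streamlines",
    "lesion_streamline_budget",
    "greedy_merge",
    "log_transform",
    "inverse_log_transform",
    "weighted_degree_distribution",
    "fit_powerlaw_tail",
]


@dataclass(frozen=True)
class Connectome:
    """Weighted undirected connectivity matrix over atlas labels.

    ``active_mask`` marks atlas labels that actually carry signal (the
    170-label dialect has 4 empty labels kept for compatibility, leaving 166
    active nodes); inactive rows/columns must be all zero.  ``log_scale``
    records whether weights have been log(1 + w) transformed.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...]
    active_mask: np.ndarray
    log_scale: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mask = np.asarray(self.active_mask, dtype=bool)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "active_mask", mask)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        n = len(self.node_labels)
        if w.shape != (n, n) or mask.shape != (n,):
            raise ValueError("weights/active_mask shape must match node_labels")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("connectome must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectome must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        inactive = ~mask
        if np.any(w[inactive, :] != 0) or np.any(w[:, inactive] != 0):
            raise ValueError("inactive labels must have all-zero rows/columns")

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def _check_compatible(self, other: "Connectome") -> None:
        if self.node_labels != other.node_labels:
            raise ValueError("connectomes use different label sets")
        if not np.array_equal(self.active_mask, other.active_mask):
            raise ValueError("connectomes use different active masks")
        if self.log_scale != other.log_scale:
            raise ValueError("connectomes are on different weight scales")


@dataclass(frozen=True)
class LesionBudget:
    """Streamline count to seed in the lesion: mean over the healthy cohort."""

    n_streamlines: int
    per_control_counts: tuple[int, ...]


@dataclass(frozen=True)
class PowerLawFit:
    """Continuous MLE fit of a distribution tail, P(x) ~ x^-alpha for x >= xmin."""

    alpha: float
    xmin: float
    ks_distance: float
    alpha_se: float
    n_tail: int


def intersect_streamlines(
    streamlines: Sequence[np.ndarray], lesion: Iterable[Voxel]
) -> int:
    """Count streamlines with at least one vertex inside the lesion voxel set.

    A vertex belongs to the voxel obtained by flooring its coordinates
    (vertex-in-voxel membership; adequate at sub-voxel integration steps).
    An empty lesion yields 0.
    """
    lesion_set = set(lesion)
    if not lesion_set:
        return 0
    count = 0
    for line in streamlines:
        pts = np.asarray(line, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
            raise ValueError("each streamline must be a non-empty (k, 3) polyline")
        voxels = np.floor(pts).astype(int)
        if any(tuple(v) in lesion_set for v in voxels):
            count += 1
    return count


def lesion_streamline_budget(per_control_counts: Sequence[int]) -> LesionBudget:
    """Average lesion-crossing streamline count, rounded half-up to an integer."""
    counts = tuple(int(c) for c in per_control_counts)
    if not counts:
        raise ValueError("need at least one control count")
    if any(c < 0 for c in counts):
        raise ValueError("streamline counts must be non-negative")
    mean = sum(counts) / len(counts)
    return LesionBudget(n_streamlines=int(math.floor(mean + 0.5)), per_control_counts=counts)


def greedy_merge(healthy: Connectome, lesion: Connectome) -> Connectome:
    """Edgewise maximum of the healthy and lesion matrices.

    Keeps, for every pair of regions, the stronger of the two reconstructions;
    commutative, idempotent and monotone by construction.
    """
    healthy._check_compatible(lesion)
    return replace(healthy, weights=np.maximum(healthy.weights, lesion.weights))


def log_transform(c: Connectome) -> Connectome:
    """Normalize native streamline weights as log(1 + w).

    Prevents numerical overflow from ~1e3 streamline counts and enhances
    differences among weaker connections.
    """
    if c.log_scale:
        raise ValueError("connectome is already log-scaled")
    return replace(c, weights=np.log1p(c.weights), log_scale=True)


def inverse_log_transform(c: Connectome) -> Connectome:
    """Undo the log(1 + w) normalization: w = exp(x) - 1."""
    if not c.log_scale:
        raise ValueError("connectome is already on the native scale")
    return replace(c, weights=np.expm1(c.weights), log_scale=False)


def weighted_degree_distribution(c: Connectome) -> np.ndarray:
    """Sum of incident native weights for each active node."""
    if c.log_scale:
        raise ValueError("weighted degrees are defined on the native scale")
    return c.weights.sum(axis=1)[c.active_mask]


def _ks_distance(tail: np.ndarray, alpha: float, xmin: float) -> float:
    n = tail.size
    ecdf = np.arange(1, n + 1) / n
    model = 1.0 - (tail / xmin) ** (1.0 - alpha)
    return float(np.max(np.abs(ecdf - model)))


def fit_powerlaw_tail(
    values: Sequence[float], xmin: float | None = None
) -> PowerLawFit:
    """Fit the tail of a distribution to a power law.

    Continuous maximum likelihood: alpha = 1 + n / sum(ln(x_i / xmin)) over
    the tail x >= xmin.  When ``xmin`` is not supplied it is chosen among the
    observed values to minimize the Kolmogorov-Smirnov distance D between the
    empirical tail and the fitted model.  The exponent's standard error is
    sigma = (alpha - 1) / sqrt(n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[x > 0]
    if x.size < 10:
        raise ValueError("need at least 10 positive values to fit a tail")

    def fit_at(candidate: float) -> PowerLawFit | None:
        tail = x[x >= candidate]
        n = tail.size
        if n < 2:
            return None
        log_sum = float(np.log(tail / candidate).sum())
        if log_sum <= 0:
            return None
        alpha = 1.0 + n / log_sum
        return PowerLawFit(
            alpha=alpha,
            xmin=float(candidate),
            ks_distance=_ks_distance(tail, alpha, candidate),
            alpha_se=(alpha - 1.0) / math.sqrt(n),
            n_tail=n,
        )

    if xmin is not None:
        fit = fit_at(float(xmin))
        if fit is None:
            raise ValueError("insufficient tail points above the supplied xmin")
        return fit
    candidates = np.unique(x)[:-1]  # keep >=2 tail points
    fits = [f for f in (fit_at(c) for c in candidates) if f is not None]
    if not fits:
        raise ValueError("no viable xmin candidate (degenerate tail)")
    return min(fits, key=lambda f: f.ks_distance)
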