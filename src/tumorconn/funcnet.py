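"""Functional connectivity matrices and network scores.

A functional network is the matrix of pairwise Pearson correlations between
regional BOLD series.  Scores implemented here:

* Theta richness — how far the distribution of correlations is from uniform
  (1 = maximally rich, 0 = all correlations in a single histogram bin);
* delta-theta — patient richness minus a healthy reference richness;
* node similarity — mean row-wise correlation between a patient network and a
  pool of healthy networks (diagonal entries removed);
* tumor/DMN voxel overlap and tumor-to-region centroid distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectral import BoldSeries

Voxel = tuple[int, int, int]

__all__ = [
    "FunctionalNetwork",
    "RichnessScore",
    "OverlapScore",
    "extract_mean_series",
    "build_fc_matrix",
    "theta_richness",
    "delta_theta",
    "node_similarity",
    "tumor_dmn_overlap",
    "centroid_distance",
    "mean_network",
]


@dataclass(frozen=True)
class FunctionalNetwork:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    matrix: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        n = len(self.region_ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match region_ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(m < -1 - 1e-10) or np.any(m > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.matrix[iu]


@dataclass(frozen=True)
class RichnessScore:
    theta: float
    m: int
    histogram: np.ndarray
    delta_theta: float | None = None


@dataclass(frozen=True)
class OverlapScore:
    value: float
    tumor_voxels_in_dmn: int
    dmn_voxels: int


def extract_mean_series(
    voxel_series: Mapping[Voxel, BoldSeries], mask: Iterable[Voxel]
) -> BoldSeries:
    """Voxel-wise mean BOLD series over a binary mask."""
    mask = list(mask)
    if not mask:
        raise ValueError("mask is empty")
    missing = [v for v in mask if v not in voxel_series]
    if missing:
        raise ValueError(f"mask voxels not covered by voxel_series: {missing[:3]}...")
    series = [voxel_series[v] for v in mask]
    tr = series[0].tr_seconds
    if any(not math.isclose(s.tr_seconds, tr) for s in series):
        raise ValueError("all voxel series must share a repetition time")
    stacked = np.stack([s.values for s in series])
    return BoldSeries(values=stacked.mean(axis=0), tr_seconds=tr)


def build_fc_matrix(series: Mapping[str, BoldSeries]) -> FunctionalNetwork:
    """Pairwise Pearson correlations between regional BOLD series."""
    if len(series) < 2:
        raise ValueError("need at least two regions")
    region_ids = tuple(series.keys())
    lengths = {series[r].n_volumes for r in region_ids}
    if len(lengths) != 1:
        raise ValueError("series lengths differ; harmonize them first")
    data = np.stack([series[r].values for r in region_ids])
    stds = data.std(axis=1)
    dead = [region_ids[i] for i in np.nonzero(stds == 0)[0]]
    if dead:
        raise ValueError(f"zero-variance region(s): {dead}")
    matrix = np.corrcoef(data)
    matrix = 0.5 * (matrix + matrix.T)
    np.fill_diagonal(matrix, 1.0)
    return FunctionalNetwork(matrix=np.clip(matrix, -1.0, 1.0), region_ids=region_ids)


def theta_richness(net: FunctionalNetwork, m: int = 15) -> RichnessScore:
    """Theta richness of a functional network.

    The off-diagonal correlations are histogrammed into ``m`` equal-width bins
    on the fixed support [-1, 1] (fixed so the score is comparable across
    subjects) and compared with the uniform histogram:

        theta = 1 - m / (2 (m - 1)) * sum_mu | P_mu - 1/m |

    theta = 1 when the correlations fill all bins uniformly and 0 when they
    collapse into a single bin; sensible bin counts range from 10 to 20.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    values = net.upper_triangle()
    if values.size < 2:
        raise ValueError("need at least two off-diagonal correlations")
    counts, _ = np.histogram(values, bins=m, range=(-1.0, 1.0))
    hist = counts / counts.sum()
    theta = 1.0 - m / (2.0 * (m - 1)) * float(np.abs(hist - 1.0 / m).sum())
    return RichnessScore(theta=float(theta), m=m, histogram=hist)


def delta_theta(patient: RichnessScore, healthy_reference: RichnessScore) -> float:
    """Signed richness change, theta_patient - theta_healthy (same m)."""
    if patient.m != healthy_reference.m:
        raise ValueError("richness scores use different bin counts")
    return patient.theta - healthy_reference.theta


def mean_network(networks: Sequence[FunctionalNetwork]) -> FunctionalNetwork:
    """Entrywise mean of functional networks (the healthy reference)."""
    if not networks:
        raise ValueError("need at least one network")
    ids = networks[0].region_ids
    if any(n.region_ids != ids for n in networks):
        raise ValueError("networks cover different region sets")
    mean = np.mean([n.matrix for n in networks], axis=0)
    np.fill_diagonal(mean, 1.0)
    return FunctionalNetwork(matrix=mean, region_ids=ids)


def node_similarity(
    patient: FunctionalNetwork, healthy: Sequence[FunctionalNetwork]
) -> tuple[float, float]:
    """Row-wise similarity of a patient network to a healthy pool.

    For every node and every healthy network, the Pearson correlation between
    the two matrix rows with the diagonal entry removed (the unit diagonal
    would otherwise inflate the correlation).  Returns the mean and SEM over
    all (node, healthy-subject) pairs.
    """
    if not healthy:
        raise ValueError("healthy pool is empty")
    ids = patient.region_ids
    if any(h.region_ids != ids for h in healthy):
        raise ValueError("region sets/order differ between patient and healthy pool")
    n = patient.n_regions
    sims: list[float] = []
    for h in healthy:
        for node in range(n):
            keep = np.arange(n) != node
            a = patient.matrix[node, keep]
            b = h.matrix[node, keep]
            sims.append(float(np.corrcoef(a, b)[0, 1]))
    arr = np.asarray(sims)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def tumor_dmn_overlap(tumor: Iterable[Voxel], dmn: Iterable[Voxel]) -> OverlapScore:
    """Fraction of the DMN volume occupied by the tumor: |T intersect D| / |D|."""
    tumor_set, dmn_set = set(tumor), set(dmn)
    if not dmn_set:
        raise ValueError("DMN voxel set is empty")
    inter = len(tumor_set & dmn_set)
    return OverlapScore(
        value=inter / len(dmn_set), tumor_voxels_in_dmn=inter, dmn_voxels=len(dmn_set)
    )


def centroid_distance(
    tumor: Iterable[Voxel], dmn_regions: Sequence[Iterable[Voxel]]
) -> tuple[float, float]:
    """Mean Euclidean distance from the tumor centroid to each region centroid."""
    tumor_arr = np.asarray(list(tumor), dtype=float)
    if tumor_arr.size == 0:
        raise ValueError("tumor voxel set is empty")
    t_centroid = tumor_arr.mean(axis=0)
    dists = []
    for region in dmn_regions:
        arr = np.asarray(list(region), dtype=float)
        if arr.size == 0:
            raise ValueError("empty DMN region")
        dists.append(float(np.linalg.norm(arr.mean(axis=0) - t_centroid)))
    darr = np.asarray(dists)
    sem = float(darr.std(ddof=1) / math.sqrt(darr.size)) if darr.size > 1 else 0.0
    return float(darr.mean()), sem
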