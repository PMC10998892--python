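"""Synthetic cohort generator.

The real study rests on an fMRI + diffusion cohort that cannot be shipped with
the package, so every input the analysis consumes is emulated here with known
ground truth:

* regional BOLD series (~183 volumes, repetition times 2.1 s / 2.4 s assigned
  round-robin) built from a sinusoid comb whose per-frequency power follows a
  tilt-controlled power-law envelope — positive tilt shifts power toward low
  frequencies (slower dynamics), negative toward high frequencies;
* voxelized tumor masks (connected blobs on an abstract integer lattice) and
  disjoint default-mode-network region masks, with controllable tumor/DMN
  overlap;
* healthy/patient connectome cohorts sharing a lognormal-weighted template
  backbone, with a lesion-dependent tracking dropout (healthy-branch versus
  lesion-branch matrices whose greedy merge gives the pre-surgery network) and
  a known surgery operator producing the post-surgery network.

Everything is driven by a single integer seed; identical seed + config yields
a bitwise-identical cohort.  These distributional choices are stand-ins for
real data, not estimates from it — see the methods note for what they do and
do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import Connectome, greedy_merge
from .spectral import BoldSeries

Voxel = tuple[int, int, int]

LESION_LABELS = ("frontal", "temporal", "parietal")

__all__ = [
    "SimulationConfig",
    "SyntheticSubject",
    "LESION_LABELS",
    "generate_bold",
    "generate_masks",
    "dmn_region_masks",
    "generate_connectome_cohort",
    "lesion_node_block",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study-condition defaults."""

    seed: int = 0
    n_controls: int = 10
    n_patients: int = 20
    n_regions_dmn: int = 41
    n_volumes: int = 183
    tr_choices: tuple[float, ...] = (2.1, 2.4)  # assigned round-robin
    tilt_range: float = 2.0  # patient tilts drawn uniform in [-range, range]
    bold_noise_sigma: float = 0.2  # white noise, relative to unit signal sd
    tumor_volume_voxels: int = 150  # base volume; per patient x U[0.5, 2]
    grid_shape: tuple[int, int, int] = (36, 36, 36)
    dmn_region_side: int = 3  # cubic DMN region blobs, side in voxels
    n_atlas_labels: int = 170
    n_empty_labels: int = 4
    lognormal_mu: float = 3.0  # marginal log-weight mean (native counts ~1e1-1e3)
    lognormal_sigma: float = 1.0  # marginal log-weight standard deviation
    subject_sigma: float = 0.1  # anatomical per-subject log deviation (latent)
    scan_sigma: float = 0.2  # per-acquisition log noise, independent per scan
    backbone_density: float = 0.3
    spurious_edge_prob: float = 0.05  # per-scan false-positive edges outside
    # the backbone (reconstruction artifacts the anatomical prior filters)
    lesion_nodes_per_label: int = 8
    tumor_attenuation: float = 0.6  # lesion-branch recovery of affected edges
    msmt_lesion_dropout: float = 0.25  # healthy-branch truncation at the lesion
    surgery_attenuation: float = 0.5
    surgery_heterogeneity: float = 0.5  # per-edge attenuation exponent spread:
    # affected edge k is scaled by attenuation**u_k with u_k drawn once per
    # lesion label from U(1-h, 1+h), so resections hit connections unevenly
    # but reproducibly across subjects sharing a lesion site
    surgery_radius: int = 1  # graph hops from lesion-adjacent nodes
    periventricular_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.n_volumes < 16:
            raise ValueError("n_volumes must be at least 16")
        if self.tumor_volume_voxels <= 0:
            raise ValueError("tumor_volume_voxels must be positive")
        if not 0.0 <= self.surgery_attenuation <= 1.0:
            raise ValueError("surgery_attenuation must lie in [0, 1]")
        if not 0.0 < self.backbone_density < 1.0:
            raise ValueError("backbone_density must lie in (0, 1)")
        if self.n_atlas_labels <= self.n_empty_labels:
            raise ValueError("need at least one active atlas label")
        if any(tr <= 0 for tr in self.tr_choices):
            raise ValueError("repetition times must be positive")
        if self.surgery_radius < 1:
            raise ValueError("surgery_radius must be at least 1")
        if self.subject_sigma**2 + self.scan_sigma**2 >= self.lognormal_sigma**2:
            raise ValueError(
                "subject_sigma^2 + scan_sigma^2 must stay below lognormal_sigma^2"
            )

    @property
    def n_active(self) -> int:
        return self.n_atlas_labels - self.n_empty_labels


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated subject with its ground-truth bookkeeping."""

    subject_id: str
    role: str  # "control" | "patient"
    tr_seconds: float
    bold: dict[str, BoldSeries]
    voxel_series: dict[Voxel, BoldSeries]
    tumor_mask: frozenset[Voxel]
    pre_connectome: Connectome
    post_connectome: Connectome | None
    healthy_branch: Connectome | None  # patients: tracking without the lesion
    lesion_branch: Connectome | None  # patients: lesion-only reconstruction
    true_tilt: float
    true_surgery_edges: tuple[int, ...]  # upper-triangle edge indices (active nodes)
    lesion_label: str | None = None
    periventricular: bool = False
    tumor_volume_voxels: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("control", "patient"):
            raise ValueError("role must be 'control' or 'patient'")
        if self.role == "patient":
            if not self.tumor_mask:
                raise ValueError("patients must carry a tumor mask")
            if self.post_connectome is None:
                raise ValueError("patients must carry a post-surgery connectome")
        else:
            if self.post_connectome is not None:
                raise ValueError("controls carry no post-surgery connectome")


def _rng(seed_material: Sequence[int]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(seed_material)))


def generate_bold(
    config: SimulationConfig,
    tilt: float,
    seed: int | Sequence[int],
    tr_seconds: float | None = None,
    n_volumes: int | None = None,
    noise_sigma: float | None = None,
    k_indices: Sequence[int] | None = None,
    region_id: str | None = None,
) -> BoldSeries:
    """A zero-mean series with a tilt-controlled spectral envelope.

    Built as a comb of sinusoids on the discrete real-FFT frequency grid with
    random phases; the power of the component at frequency f is proportional
    to f**(-tilt), so positive tilt concentrates power at low frequencies.
    White noise of relative standard deviation ``noise_sigma`` is added, and
    the result is demeaned.  ``k_indices`` restricts the comb to a subset of
    harmonics (useful for closed-form checks).
    """
    n = n_volumes if n_volumes is not None else config.n_volumes
    tr = tr_seconds if tr_seconds is not None else config.tr_choices[0]
    sigma = noise_sigma if noise_sigma is not None else config.bold_noise_sigma
    if n < 16:
        raise ValueError("n_volumes must be at least 16")
    if tr <= 0:
        raise ValueError("tr_seconds must be positive")
    rng = _rng([seed] if isinstance(seed, int) else seed)
    ks = np.arange(1, (n - 1) // 2 + 1) if k_indices is None else np.asarray(k_indices)
    if np.any(ks < 1) or np.any(ks > n // 2):
        raise ValueError("k_indices must be valid non-DC harmonics")
    freqs = ks / (n * tr)
    power = freqs ** (-float(tilt))
    amps = np.sqrt(power / power.sum())
    phases = rng.uniform(0.0, 2.0 * math.pi, size=ks.size)
    t = np.arange(n)
    signal = (amps[:, None] * np.cos(2 * math.pi * ks[:, None] * t / n + phases[:, None])).sum(
        axis=0
    )
    signal = signal / signal.std() if signal.std() > 0 else signal
    if sigma > 0:
        signal = signal + sigma * rng.standard_normal(n)
    signal = signal - signal.mean()
    return BoldSeries(values=signal, tr_seconds=tr, region_id=region_id)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def dmn_region_masks(config: SimulationConfig) -> list[frozenset[Voxel]]:
    """Disjoint cubic DMN region blobs on a coarse placement lattice."""
    side = config.dmn_region_side
    spacing = side + 3  # gaps keep regions disjoint and leave room for tumors
    nx, ny, nz = config.grid_shape
    # keep blobs off the grid boundary so any blob voxel connects to free
    # space (a tumor growing out of a blob can then never be stranded)
    slots = [
        (x, y, z)
        for x in range(1, nx - side, spacing)
        for y in range(1, ny - side, spacing)
        for z in range(1, nz - side, spacing)
    ]
    if len(slots) < config.n_regions_dmn:
        raise ValueError("voxel grid too small for the requested DMN regions")
    regions = []
    for ox, oy, oz in slots[: config.n_regions_dmn]:
        regions.append(
            frozenset(
                (ox + dx, oy + dy, oz + dz)
                for dx in range(side)
                for dy in range(side)
                for dz in range(side)
            )
        )
    return regions


def _neighbors(v: Voxel, shape: tuple[int, int, int]) -> list[Voxel]:
    out = []
    for axis in range(3):
        for step in (-1, 1):
            w = list(v)
            w[axis] += step
            if 0 <= w[axis] < shape[axis]:
                out.append(tuple(w))
    return out


def _staircase(a: Voxel, b: Voxel) -> list[Voxel]:
    """Axis-aligned lattice path from a to b (excluding a, including b)."""
    path = []
    cur = list(a)
    for axis in range(3):
        step = 1 if b[axis] > cur[axis] else -1
        while cur[axis] != b[axis]:
            cur[axis] += step
            path.append(tuple(cur))
    return path


def generate_masks(
    config: SimulationConfig,
    seed: int | Sequence[int],
    overlap_fraction: float = 0.0,
    tumor_volume: int | None = None,
) -> tuple[frozenset[Voxel], list[frozenset[Voxel]]]:
    """A connected tumor blob and the DMN region masks.

    ``overlap_fraction`` controls |tumor intersect DMN| / |DMN| exactly, from
    0 (tumor avoids the DMN) to 1 (tumor covers every DMN voxel).  Raises if
    the requested volume cannot accommodate the requested overlap or does not
    fit in the grid.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    volume = tumor_volume if tumor_volume is not None else config.tumor_volume_voxels
    if volume <= 0:
        raise ValueError("tumor volume must be positive")
    rng = _rng([seed] if isinstance(seed, int) else seed)
    regions = dmn_region_masks(config)
    dmn_all: set[Voxel] = set().union(*regions)
    target_in = int(round(overlap_fraction * len(dmn_all)))
    if target_in > volume:
        raise ValueError("requested overlap infeasible for the given tumor volume")

    shape = config.grid_shape
    tumor: set[Voxel] = set()
    in_count = 0

    if target_in > 0:
        # Walk DMN voxels in deterministic order, connecting them with
        # axis-aligned paths; every DMN voxel swallowed en route counts.
        dmn_ordered = [v for region in regions for v in sorted(region)]
        start = dmn_ordered[0]
        tumor.add(start)
        in_count = 1
        for target in dmn_ordered:
            if in_count >= target_in:
                break
            if target in tumor:
                continue
            anchor = min(tumor, key=lambda v: sum(abs(v[i] - target[i]) for i in range(3)))
            for step_voxel in _staircase(anchor, target):
                if in_count >= target_in:
                    break
                if step_voxel in tumor:
                    continue
                tumor.add(step_voxel)
                if step_voxel in dmn_all:
                    in_count += 1
        if in_count < target_in or len(tumor) > volume:
            raise ValueError("requested overlap infeasible for the given tumor volume")
    else:
        candidates = [
            (x, y, z)
            for x in range(shape[0])
            for y in range(shape[1])
            for z in range(shape[2])
            if (x, y, z) not in dmn_all
        ]
        tumor.add(candidates[rng.integers(len(candidates))])

    # Grow the blob to the requested volume without touching further DMN voxels.
    frontier = [w for v in tumor for w in _neighbors(v, shape) if w not in tumor]
    frontier = [w for w in frontier if w not in dmn_all]
    seen = set(frontier)
    while len(tumor) < volume:
        if not frontier:
            raise ValueError("tumor volume does not fit in the grid at this overlap")
        idx = int(rng.integers(len(frontier)))
        voxel = frontier.pop(idx)
        tumor.add(voxel)
        for w in _neighbors(voxel, shape):
            if w not in tumor and w not in seen and w not in dmn_all:
                frontier.append(w)
                seen.add(w)
    return frozenset(tumor), regions


# ---------------------------------------------------------------------------
# Connectome cohort
# ---------------------------------------------------------------------------


def lesion_node_block(config: SimulationConfig, lesion_label: str) -> np.ndarray:
    """Active-node indices structurally adjacent to a lesion of this label.

    Each lobe label maps to a fixed, disjoint block of nodes so that the
    surgery operator is consistent across subjects sharing a label.
    """
    i = LESION_LABELS.index(lesion_label)
    k = config.lesion_nodes_per_label
    if (i + 1) * k > config.n_active:
        raise ValueError("not enough active nodes for the lesion blocks")
    return np.arange(i * k, (i + 1) * k)


def _edge_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _affected_edges(
    backbone: np.ndarray, lesion_nodes: np.ndarray, radius: int, n: int
) -> np.ndarray:
    """Boolean mask (over upper-triangle edges) of surgery-affected edges.

    Nodes within ``radius - 1`` backbone hops of a lesion node form the
    affected set; an edge is affected when either endpoint is in that set.
    """
    affected_nodes = np.zeros(n, dtype=bool)
    affected_nodes[lesion_nodes] = True
    adj = np.zeros((n, n), dtype=bool)
    iu, ju = _edge_index(n)
    adj[iu, ju] = backbone
    adj |= adj.T
    for _ in range(radius - 1):
        affected_nodes = affected_nodes | adj[affected_nodes].any(axis=0)
    return affected_nodes[iu] | affected_nodes[ju]


def _embed(
    active_vec: np.ndarray, config: SimulationConfig, labels: tuple[str, ...], log_scale=False
) -> Connectome:
    """Upper-triangle vector over active nodes -> full atlas Connectome."""
    n_act = config.n_active
    iu, ju = _edge_index(n_act)
    mat_act = np.zeros((n_act, n_act))
    mat_act[iu, ju] = active_vec
    mat_act = mat_act + mat_act.T
    n = config.n_atlas_labels
    active_mask = np.zeros(n, dtype=bool)
    active_mask[:n_act] = True  # empty labels kept last, for compatibility
    mat = np.zeros((n, n))
    mat[:n_act, :n_act] = mat_act
    return Connectome(weights=mat, node_labels=labels, active_mask=active_mask, log_scale=log_scale)


def generate_connectome_cohort(
    config: SimulationConfig, seed: int | None = None
) -> list[SyntheticSubject]:
    """The full synthetic cohort: controls and pre/post-surgery patients.

    All subjects share a sparse template backbone with lognormal edge weights
    (plus rare subject-specific spurious edges), so a thresholded healthy
    average is an informative anatomical prior.  Each subject carries a latent
    anatomical matrix (template + per-subject deviation); every measured
    matrix additionally receives independent per-scan multiplicative noise,
    because pre- and post-surgery networks come from different acquisitions.
    Patient pre-surgery matrices are built in two branches mimicking the
    hybrid reconstruction: a healthy branch whose lesion-adjacent edges are
    strongly truncated and a lesion branch recovering those edges (attenuated
    by ``tumor_attenuation``); their greedy merge is the pre-surgery network.
    The surgery operator further attenuates the affected edges by
    ``surgery_attenuation``; with the per-scan noise this makes the post
    matrix equal the surgery-transformed pre matrix times multiplicative
    lognormal noise.
    """
    if config.n_controls < 2 or config.n_patients < 2:
        raise ValueError("need at least 2 controls and 2 patients")
    base_seed = config.seed if seed is None else seed
    n_act = config.n_active
    n_edges = n_act * (n_act - 1) // 2
    labels = tuple(f"ROI_{i + 1:03d}" for i in range(config.n_atlas_labels))

    rng_cohort = _rng([base_seed, 0])
    backbone = rng_cohort.random(n_edges) < config.backbone_density
    # Template spread is reduced so that template + subject deviation +
    # per-scan noise has the configured marginal lognormal_sigma.
    template_sd = math.sqrt(
        config.lognormal_sigma**2 - config.subject_sigma**2 - config.scan_sigma**2
    )
    template_logw = rng_cohort.normal(config.lognormal_mu, template_sd, n_edges)
    # per-label surgery attenuation exponents, fixed for the whole cohort
    h = config.surgery_heterogeneity
    surgery_exponents = {
        label: _rng([base_seed, 5, i]).uniform(1.0 - h, 1.0 + h, n_edges)
        for i, label in enumerate(LESION_LABELS)
    }

    subjects: list[SyntheticSubject] = []
    n_total = config.n_controls + config.n_patients
    for idx in range(n_total):
        is_patient = idx >= config.n_controls
        role = "patient" if is_patient else "control"
        sid = f"sub-PAT{idx - config.n_controls + 1:02d}" if is_patient else f"sub-CON{idx + 1:02d}"
        tr = config.tr_choices[idx % len(config.tr_choices)]
        rng_s = _rng([base_seed, 1, idx])

        # --- structural matrices -----------------------------------------
        # latent anatomy: template backbone + per-subject deviation
        base = np.zeros(n_edges)
        base[backbone] = np.exp(
            template_logw[backbone]
            + config.subject_sigma * rng_s.standard_normal(int(backbone.sum()))
        )

        def measure(latent: np.ndarray) -> np.ndarray:
            """One acquisition: multiplicative scan noise + spurious edges."""
            out = latent.copy()
            if config.scan_sigma > 0:
                out *= np.exp(config.scan_sigma * rng_s.standard_normal(n_edges))
            spurious = (~backbone) & (rng_s.random(n_edges) < config.spurious_edge_prob)
            out[spurious] = np.exp(
                rng_s.normal(config.lognormal_mu, config.lognormal_sigma, int(spurious.sum()))
            )
            return out

        if is_patient:
            pat_i = idx - config.n_controls
            lesion_label = LESION_LABELS[pat_i % len(LESION_LABELS)]
            periventricular = bool(rng_s.random() < config.periventricular_prob)
            tilt = float(rng_s.uniform(-config.tilt_range, config.tilt_range))
            lesion_nodes = lesion_node_block(config, lesion_label)
            affected = _affected_edges(backbone, lesion_nodes, config.surgery_radius, n_act)

            # pre-surgery scan: both branches come from the same acquisition
            measured = measure(base)
            healthy_vec = measured.copy()
            healthy_vec[affected] *= config.msmt_lesion_dropout
            lesion_vec = np.zeros(n_edges)
            lesion_vec[affected] = measured[affected] * config.tumor_attenuation
            healthy_c = _embed(healthy_vec, config, labels)
            lesion_c = _embed(lesion_vec, config, labels)
            pre_c = greedy_merge(healthy_c, lesion_c)

            # post-surgery scan: surgery acts on the tumor-affected anatomy,
            # measured with its own independent acquisition
            post_base = base.copy()
            atten = config.surgery_attenuation ** surgery_exponents[lesion_label]
            post_base[affected] *= config.tumor_attenuation * atten[affected]
            post_c = _embed(measure(post_base), config, labels)
            true_edges = tuple(int(e) for e in np.nonzero(affected & (base > 0))[0])

            volume = int(
                round(config.tumor_volume_voxels * rng_s.uniform(0.5, 2.0))
            )
            dmn_total = config.n_regions_dmn * config.dmn_region_side**3
            # keep half the volume for connecting tissue outside the DMN
            overlap = float(rng_s.uniform(0.0, min(0.25, 0.5 * volume / dmn_total)))
            tumor_mask, dmn_regions = generate_masks(
                config, [base_seed, 2, idx], overlap_fraction=overlap, tumor_volume=volume
            )
        else:
            lesion_label = None
            periventricular = False
            tilt = 0.0
            tumor_mask = frozenset()
            dmn_regions = None
            healthy_c = lesion_c = post_c = None
            pre_c = _embed(measure(base), config, labels)
            true_edges = ()
            volume = 0

        # --- BOLD ---------------------------------------------------------
        bold = {
            f"DMN_{r + 1:02d}": generate_bold(
                config,
                tilt,
                [base_seed, 3, idx, r],
                tr_seconds=tr,
                region_id=f"DMN_{r + 1:02d}",
            )
            for r in range(config.n_regions_dmn)
        }
        voxel_series: dict[Voxel, BoldSeries] = {}
        if is_patient:
            for k, voxel in enumerate(sorted(tumor_mask)):
                voxel_series[voxel] = generate_bold(
                    config, tilt, [base_seed, 4, idx, k], tr_seconds=tr
                )

        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                role=role,
                tr_seconds=tr,
                bold=bold,
                voxel_series=voxel_series,
                tumor_mask=tumor_mask,
                pre_connectome=pre_c,
                post_connectome=post_c,
                healthy_branch=healthy_c,
                lesion_branch=lesion_c,
                true_tilt=tilt,
                true_surgery_edges=true_edges,
                lesion_label=lesion_label,
                periventricular=periventricular,
                tumor_volume_voxels=volume,
            )
        )
    return subjects
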