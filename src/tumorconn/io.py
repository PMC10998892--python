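"""Plain-text readers and writers for the pipeline's file formats.

Everything is text: BOLD series as TSV (rows = time points, columns =
regions) with a JSON sidecar carrying the repetition time; voxel masks as
3-column integer CSV; connectomes as dense TSV with a node-label header and a
JSON sidecar for the active mask and scale flag; tractogram streamlines as a
multi-polyline text format (one "x y z" vertex per line, polylines separated
by blank lines); the cohort as a directory tree with a JSON manifest.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assembly import Connectome
from .spectral import BoldSeries
from .synthetic import SimulationConfig, SyntheticSubject

Voxel = tuple[int, int, int]

FLOAT_FMT = "%.17g"  # lossless float round trip, byte-stable across runs


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------


def write_bold_tsv(path: Path, series: Mapping[str, BoldSeries]) -> None:
    """Time-by-region TSV plus a sidecar ``<stem>.json`` with tr_seconds."""
    regions = list(series.keys())
    trs = {series[r].tr_seconds for r in regions}
    if len(trs) != 1:
        raise ValueError("all regions of one subject must share a repetition time")
    data = np.column_stack([series[r].values for r in regions])
    header = "\t".join(regions)
    np.savetxt(path, data, fmt=FLOAT_FMT, delimiter="\t", header=header, comments="")
    sidecar = {"tr_seconds": float(next(iter(trs)))}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_bold_tsv(path: Path) -> dict[str, BoldSeries]:
    sidecar = json.loads(path.with_suffix(".json").read_text())
    tr = float(sidecar["tr_seconds"])
    with open(path) as fh:
        regions = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return {
        region: BoldSeries(values=data[:, j], tr_seconds=tr, region_id=region)
        for j, region in enumerate(regions)
    }


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def write_mask_csv(path: Path, mask: Iterable[Voxel]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z"])
        for voxel in sorted(mask):
            writer.writerow(voxel)


def read_mask_csv(path: Path) -> frozenset[Voxel]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        return frozenset((int(x), int(y), int(z)) for x, y, z in reader)


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------


def write_connectome_tsv(path: Path, c: Connectome) -> None:
    header = "\t".join(c.node_labels)
    np.savetxt(path, c.weights, fmt=FLOAT_FMT, delimiter="\t", header=header, comments="")
    sidecar = {
        "active_mask": [bool(a) for a in c.active_mask],
        "log_scale": c.log_scale,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar) + "\n")


def read_connectome_tsv(path: Path) -> Connectome:
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with open(path) as fh:
        labels = tuple(fh.readline().strip().split("\t"))
    weights = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return Connectome(
        weights=weights,
        node_labels=labels,
        active_mask=np.asarray(sidecar["active_mask"], dtype=bool),
        log_scale=bool(sidecar["log_scale"]),
    )


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------


def write_streamlines(path: Path, streamlines: Sequence[np.ndarray]) -> None:
    with open(path, "w") as fh:
        for k, line in enumerate(streamlines):
            if k:
                fh.write("\n")
            for vertex in np.asarray(line, dtype=float):
                fh.write(" ".join(FLOAT_FMT % v for v in vertex) + "\n")


def read_streamlines(path: Path) -> list[np.ndarray]:
    lines: list[np.ndarray] = []
    current: list[list[float]] = []
    for raw in path.read_text().splitlines():
        raw = raw.strip()
        if not raw:
            if current:
                lines.append(np.asarray(current))
                current = []
            continue
        current.append([float(v) for v in raw.split()])
    if current:
        lines.append(np.asarray(current))
    return lines


# ---------------------------------------------------------------------------
# Cohort tree
# ---------------------------------------------------------------------------


def write_cohort(cohort_dir: Path, subjects: Sequence[SyntheticSubject],
                 config: SimulationConfig) -> None:
    """Per-subject directories plus a JSON manifest at the root."""
    cohort_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        sdir = cohort_dir / s.subject_id
        sdir.mkdir(exist_ok=True)
        write_bold_tsv(sdir / "bold.tsv", s.bold)
        if s.tumor_mask:
            write_mask_csv(sdir / "tumor_mask.csv", s.tumor_mask)
        write_connectome_tsv(sdir / "pre_connectome.tsv", s.pre_connectome)
        if s.post_connectome is not None:
            write_connectome_tsv(sdir / "post_connectome.tsv", s.post_connectome)
        if s.healthy_branch is not None:
            write_connectome_tsv(sdir / "healthy_branch.tsv", s.healthy_branch)
        if s.lesion_branch is not None:
            write_connectome_tsv(sdir / "lesion_branch.tsv", s.lesion_branch)
        meta = {
            "subject_id": s.subject_id,
            "role": s.role,
            "tr_seconds": s.tr_seconds,
            "true_tilt": s.true_tilt,
            "lesion_label": s.lesion_label,
            "periventricular": s.periventricular,
            "tumor_volume_voxels": s.tumor_volume_voxels,
            "true_surgery_edges": list(s.true_surgery_edges),
        }
        (sdir / "subject.json").write_text(json.dumps(meta, indent=2) + "\n")
    manifest = {
        "subjects": [s.subject_id for s in subjects],
        "config": dataclasses.asdict(config),
    }
    (cohort_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_cohort(cohort_dir: Path) -> tuple[list[SyntheticSubject], SimulationConfig]:
    """Load a cohort tree written by :func:`write_cohort`.

    Voxel-level BOLD series are not persisted; reloaded subjects carry an
    empty ``voxel_series`` map.
    """
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    for key in ("tr_choices", "grid_shape"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimulationConfig(**cfg_dict)
    subjects = []
    for sid in manifest["subjects"]:
        sdir = cohort_dir / sid
        meta = json.loads((sdir / "subject.json").read_text())
        mask_path = sdir / "tumor_mask.csv"
        post_path = sdir / "post_connectome.tsv"
        healthy_path = sdir / "healthy_branch.tsv"
        lesion_path = sdir / "lesion_branch.tsv"
        subjects.append(
            SyntheticSubject(
                subject_id=meta["subject_id"],
                role=meta["role"],
                tr_seconds=float(meta["tr_seconds"]),
                bold=read_bold_tsv(sdir / "bold.tsv"),
                voxel_series={},
                tumor_mask=read_mask_csv(mask_path) if mask_path.exists() else frozenset(),
                pre_connectome=read_connectome_tsv(sdir / "pre_connectome.tsv"),
                post_connectome=read_connectome_tsv(post_path) if post_path.exists() else None,
                healthy_branch=read_connectome_tsv(healthy_path) if healthy_path.exists() else None,
                lesion_branch=read_connectome_tsv(lesion_path) if lesion_path.exists() else None,
                true_tilt=float(meta["true_tilt"]),
                true_surgery_edges=tuple(meta["true_surgery_edges"]),
                lesion_label=meta["lesion_label"],
                periventricular=bool(meta["periventricular"]),
                tumor_volume_voxels=int(meta["tumor_volume_voxels"]),
            )
        )
    return subjects, config
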