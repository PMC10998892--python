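"""Simulate the synthetic study cohort.

Generates the default cohort — 10 controls and 20 tumor patients with known
spectral tilts, voxelized tumor masks, and pre/post-surgery connectomes under
a known surgery operator — and writes it as a plain-text directory tree.
The cohort tree is bulky, so it lives under scratch/; downstream scripts read
it from there.
"""

import sys
from collections import Counter
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"

from tumorconn import io as tio
from tumorconn.synthetic import SimulationConfig, generate_connectome_cohort


def main() -> None:
    config = SimulationConfig(seed=1)
    subjects = generate_connectome_cohort(config)
    tio.write_cohort(SCRATCH / "cohort", subjects, config)

    patients = [s for s in subjects if s.role == "patient"]
    print(f"cohort: {config.n_controls} controls + {config.n_patients} patients")
    print(f"TR dialects: {Counter(s.tr_seconds for s in subjects)}")
    print(f"lesion labels: {Counter(p.lesion_label for p in patients)}")
    vols = sorted(p.tumor_volume_voxels for p in patients)
    print(f"tumor volumes (voxels): min {vols[0]}, median {vols[len(vols) // 2]}, max {vols[-1]}")
    print(f"ground-truth tilts span [{min(p.true_tilt for p in patients):+.2f}, "
          f"{max(p.true_tilt for p in patients):+.2f}]")
    print(f"written to {SCRATCH / 'cohort'}")


if __name__ == "__main__":
    sys.exit(main())
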