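"""Measure the four vessel statistics for every QC-passed eye.

For each eye: fit the OD minimum enclosing circle, build the 2-4x radius
analysis ring, clip the vessel mask, skeletonize, extract and prune the
centerline graph, then measure mean bifurcation angle, vessel density,
box-counting fractal dimension, and Hart tortuosity.  Writes
results/metrics.csv (one row per eye; missing metrics are empty).

Usage: python analysis/03_measure_morphometry.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

from vesselmorph.io_qc import read_manifest
from vesselmorph.morphometry import MorphometryConfig, analyze_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    manifest = read_manifest(args.cohort / "manifest.csv")
    metrics, qc = analyze_cohort(manifest, MorphometryConfig())
    out = ROOT / "results" / "metrics.csv"
    out.parent.mkdir(exist_ok=True)
    metrics.to_csv(out, index=False)
    analyzed = metrics["qc_passed"].sum()
    print(f"measured {analyzed}/{len(metrics)} eyes -> {out}")
    print(metrics.groupby("group_label")[
        ["vessel_angle_mean", "vessel_density", "fractal_dimension", "tortuosity"]
    ].mean().round(4).to_string())


if __name__ == "__main__":
    main()
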