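"""Apply the optic-disc-centering selection rule to every cohort frame.

A frame passes when the center of the OD minimum enclosing circle lies
within one quarter of the image width of the image center.  Writes one row
per eye to results/qc.csv; failed frames are recorded, not dropped.

Usage: python analysis/02_qc_gate.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

from vesselmorph.io_qc import gate_frame, load_frame, qc_table, read_manifest

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    manifest = read_manifest(args.cohort / "manifest.csv")
    results = []
    for _, row in manifest.iterrows():
        frame = load_frame(row["vessel_path"], row["od_path"],
                           row["eye_id"], row["group"])
        results.append(gate_frame(frame))
    df = qc_table(results)
    out = ROOT / "results" / "qc.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False)
    print(f"{int(df['passed'].sum())}/{len(df)} frames passed OD-centering QC "
          f"-> {out}")
    failed = df[~df["passed"]]
    if len(failed):
        print(failed.to_string(index=False))


if __name__ == "__main__":
    main()
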