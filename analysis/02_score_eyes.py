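#!/usr/bin/env python
"""Score every synthetic eye image and summarize severity ordering.

Reads the images written by 01_simulate_data.py, detects ommatidia, computes
the distance/angle disorderliness subscores and the composite phenotypic
score per image, and reports mean composite score per condition.  Rough-eye
severity should rise monotonically with both positional jitter and dropout.

Writes results/eye_scores.tsv (per image) and results/eye_score_summary.tsv
(per condition).
"""

from pathlib import Path

import pandas as pd

from quantkit.ommatidia_score import load_image, score_image

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(
        ROOT / "results" / "synthetic" / "eye_image_manifest.tsv", sep="\t"
    )
    eye_dir = ROOT / "scratch" / "eyes"
    rows = []
    for rec in manifest.itertuples(index=False):
        scores = score_image(load_image(eye_dir / rec.file))
        rows.append({"file": rec.file, "condition": rec.condition,
                     "level": rec.level, **scores})
    scores = pd.DataFrame(rows)
    scores.to_csv(ROOT / "results" / "eye_scores.tsv", sep="\t",
                  index=False, float_format="%.4f")

    summary = (
        scores.groupby(["condition", "level"])["composite_score"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary.to_csv(ROOT / "results" / "eye_score_summary.tsv", sep="\t",
                   index=False, float_format="%.3f")
    print(summary.to_string(index=False))
    for cond, grp in summary.groupby("condition"):
        means = grp.sort_values("level")["mean"].tolist()
        trend = "monotone increasing" if all(
            b > a for a, b in zip(means, means[1:])
        ) else "NOT monotone"
        print(f"{cond}: mean composite score is {trend} across levels")


if __name__ == "__main__":
    main()
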