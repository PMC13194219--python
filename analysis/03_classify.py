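"""Classify retained compounds into emission classes.

Applies the filter cascade — DF >= 10% retention over all pooled trunk
samples, DF >= 50% in every tree before biotic stress for the constitutive
core — and the twofold rules: herbivore-induced (de novo at the infested
tree, or >= 2x versus its own pre-exposure phase and both non-infested
trees), neighbor-induced (mirror rule), stress-induced (comparable >= 2x
increases in both stressed trees).  Writes classification.csv and, when a
truth table is present in the study directory, prints the recovery of the
planted labels.
"""

import argparse
from pathlib import Path

import pandas as pd

from trunkvoc import pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "run")
    args = ap.parse_args()

    cfg = pipeline.RunConfig(
        design=str(args.study / "design.csv"), peaks=str(args.study / "peaks.csv"),
        alkanes=str(args.study / "alkanes.csv"), library=str(args.study / "library.csv"),
        calibration=str(args.study / "calibration.csv"),
        surrogates=str(args.study / "surrogates.csv"),
        out_dir=str(args.out), seed=args.seed,
    )
    bundle = pipeline.run_pipeline(cfg, write=False)
    args.out.mkdir(parents=True, exist_ok=True)
    cls = bundle["classification"]
    cls.to_csv(args.out / "classification.csv", index=False)

    print("primary labels:")
    print(cls["label"].value_counts().to_string())
    with_secondary = cls[cls["secondary_flag"] != ""]
    if len(with_secondary):
        print(f"{len(with_secondary)} constitutive compound(s) carry an induced "
              f"secondary flag: {', '.join(with_secondary['compound'])}")

    truth_path = args.study / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("compound")["true_label"]
        joined = truth.to_frame().join(cls.set_index("compound")["label"])
        joined["label"] = joined["label"].fillna("missing")
        rate = (joined["true_label"] == joined["label"]).mean()
        print(f"planted-label recovery: {100 * rate:.1f}% of {len(joined)} compounds")


if __name__ == "__main__":
    main()
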