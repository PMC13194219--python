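"""Generate the synthetic three-tree trunk-volatile study.

Writes the study tables (design, peaks, alkane ladder, compound library,
calibration levels, surrogate map, planted truth) under results/study/.
The defaults emulate the monitored design: three maples (control ApC,
infested ApI, neighbor ApN), 42 sampling days over 188 days in duplicate,
ApC stopping at day 138, with 55 planted compounds (30 constitutive,
15 herbivore-induced of which 5 de novo, 6 neighbor-induced, 4
stress-induced) plus 3 ubiquitous ambient features.
"""

import argparse
from pathlib import Path

from trunkvoc import synthetic

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()

    cfg = synthetic.default_config(seed=args.seed)
    paths = synthetic.write_study(cfg, args.out)
    truth = synthetic.truth_table(cfg)
    print(f"wrote {len(paths)} tables to {args.out}")
    print("planted classes:")
    print(truth["true_label"].value_counts().to_string())


if __name__ == "__main__":
    main()
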