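#!/usr/bin/env python
"""Score spike-in recovery of the screen against the simulation truth.

Positives are the genes planted exclusively in the target tissue; leaky
and background genes count as negatives. Writes results/evaluation.tsv.
"""

import argparse
from pathlib import Path

from texscreen.evaluation import evaluate_recovery, write_report
from texscreen.screening import read_candidates
from texscreen.simulate import read_truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--candidates", type=Path, default=Path("results/candidates.tsv"))
    parser.add_argument("--truth", type=Path, default=Path("results/fixture/truth.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/evaluation.tsv"))
    args = parser.parse_args()

    records = read_candidates(args.candidates)
    truth = read_truth(args.truth)
    report = evaluate_recovery(records.index[records["is_candidate"]], truth)
    write_report(report, args.out)

    print(f"TP={report.true_positives} FP={report.false_positives} "
          f"FN={report.false_negatives} TN={report.true_negatives}")
    print(f"precision={report.precision:.4f} recall={report.recall:.4f} "
          f"background FPR={report.false_positive_rate:.6f}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
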