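#!/usr/bin/env python
"""Characterize threshold sensitivity of the screen.

Sweeps each filter threshold through a grid around the published values
(r_min 0.99, rpkm_min 10, fc_min 5) and records candidate count,
precision and recall per configuration in results/sweep.tsv.
"""

import argparse
from pathlib import Path

from texscreen.core import read_rpkm
from texscreen.evaluation import threshold_sweep, write_sweep
from texscreen.screening import ScreenConfig
from texscreen.simulate import read_truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--rpkm", type=Path, default=Path("results/rpkm.tsv"))
    parser.add_argument("--samples", type=Path,
                        default=Path("results/fixture/samples.tsv"))
    parser.add_argument("--truth", type=Path, default=Path("results/fixture/truth.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/sweep.tsv"))
    args = parser.parse_args()

    expr = read_rpkm(args.rpkm, args.samples)
    truth = read_truth(args.truth)
    grid = (
        [ScreenConfig(r_min=r) for r in (0.90, 0.95, 0.99, 0.999)]
        + [ScreenConfig(rpkm_min=m) for m in (1.0, 5.0, 10.0, 50.0)]
        + [ScreenConfig(fc_min=f) for f in (2.0, 5.0, 20.0, 100.0)]
    )
    sweep = threshold_sweep(expr, truth, grid)
    write_sweep(sweep, args.out)

    print(sweep.to_string(index=False,
                          formatters={"precision": "{:.3f}".format,
                                      "recall": "{:.3f}".format}))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
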