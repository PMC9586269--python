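#!/usr/bin/env python
"""RPKM-normalize the fixture count matrix.

Reads results/fixture/, computes RPKM(g, j) = 1e9 * C / (N * L) with N
the library column total, and writes results/rpkm.tsv.
"""

import argparse
from pathlib import Path

from texscreen.core import read_counts, rpkm, write_rpkm


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture-dir", type=Path, default=Path("results/fixture"))
    parser.add_argument("--out", type=Path, default=Path("results/rpkm.tsv"))
    args = parser.parse_args()

    d = args.fixture_dir
    cm, genes = read_counts(d / "counts.tsv", d / "genes.tsv", d / "samples.tsv")
    expr = rpkm(cm, genes)
    write_rpkm(expr, args.out)

    target = cm.target_libraries[0]
    print(f"normalized {expr.values.shape[0]} genes x {expr.values.shape[1]} libraries")
    print(f"library totals used as N: {expr.provenance['total_counts_per_library']}")
    print(f"median RPKM in target library {target}: "
          f"{expr.values[target].median():.2f}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
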