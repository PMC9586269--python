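#!/usr/bin/env python
"""Triage screen candidates into enzyme/transport classes.

Applies the ordered annotation-keyword map to every candidate and writes
per-gene assignments (results/triage.tsv) and per-class counts
(results/summary.tsv).
"""

import argparse
from pathlib import Path

from texscreen.core import read_gene_table
from texscreen.screening import read_candidates
from texscreen.triage import summarize_classes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--candidates", type=Path, default=Path("results/candidates.tsv"))
    parser.add_argument("--genes", type=Path, default=Path("results/fixture/genes.tsv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    records = read_candidates(args.candidates)
    gene_table = read_gene_table(args.genes)
    cand_ids = records.index[records["is_candidate"]]
    assignments, summary = summarize_classes(cand_ids, gene_table)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    assignments.to_csv(args.out_dir / "triage.tsv", sep="\t")
    summary.to_csv(args.out_dir / "summary.tsv", sep="\t", index=False)

    print(f"classified {len(assignments)} candidates:")
    for _, row in summary.iterrows():
        if row["count"]:
            print(f"  {row['class_label']}: {row['count']}")
    print(f"wrote {args.out_dir / 'triage.tsv'} and {args.out_dir / 'summary.tsv'}")


if __name__ == "__main__":
    main()
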