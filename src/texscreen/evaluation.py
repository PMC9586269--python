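"""Recovery evaluation and threshold sensitivity of the screen.

On synthetic data with ground-truth labels the positives are the
``target_exclusive`` genes; ``leaky`` and ``background`` genes are
negatives (a near-exclusive gene that slips through the screen counts as
a false positive — the stringent reading of "exclusively expressed").
Undefined precision/recall (empty denominators) is reported as NaN in
memory and "NA" on disk, never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, LinkageError
from .screening import ScreenConfig, screen
from .simulate import TRUTH_TARGET_EXCLUSIVE


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and ratios of spike-in recovery."""

    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int
    precision: float  # NaN when TP+FP == 0
    recall: float  # NaN when TP+FN == 0
    n_genes: int
    config: dict | None = None
    seed: int | None = None

    @property
    def false_positive_rate(self) -> float:
        negatives = self.false_positives + self.true_negatives
        return self.false_positives / negatives if negatives else float("nan")

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d.pop("config")
        d.pop("seed")
        d["false_positive_rate"] = self.false_positive_rate
        return pd.DataFrame({"metric": list(d), "value": list(d.values())})


def evaluate_recovery(
    candidate_ids,
    truth: pd.Series,
    config: dict | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Score a candidate set against truth labels.

    ``candidate_ids`` is any iterable of gene ids (e.g. the index of the
    is_candidate subset of screen records); ``truth`` maps every gene in
    the study to its label. Candidates outside the truth gene set raise.
    """
    cand = set(candidate_ids)
    universe = set(truth.index)
    stray = cand - universe
    if stray:
        raise LinkageError(f"candidate genes absent from truth labels: {sorted(stray)[:5]}")
    positives = set(truth.index[truth == TRUTH_TARGET_EXCLUSIVE])
    tp = len(cand & positives)
    fp = len(cand - positives)
    fn = len(positives - cand)
    tn = len(universe) - tp - fp - fn
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return EvaluationReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        true_negatives=tn,
        precision=precision,
        recall=recall,
        n_genes=len(universe),
        config=config,
        seed=seed,
    )


def threshold_sweep(
    expr: ExpressionMatrix,
    truth: pd.Series,
    grid: list[ScreenConfig],
) -> pd.DataFrame:
    """Evaluate the screen at every configuration of a threshold grid.

    Returns one row per config, in grid order: thresholds, candidate
    count, precision, recall.
    """
    if not grid:
        raise ValueError("threshold grid is empty")
    rows = []
    for cfg in grid:
        records = screen(expr, cfg)
        cand = records.index[records["is_candidate"]]
        report = evaluate_recovery(cand, truth)
        rows.append(
            {
                "r_min": cfg.r_min,
                "rpkm_min": cfg.rpkm_min,
                "fc_min": cfg.fc_min,
                "epsilon": cfg.epsilon,
                "fc_mode": cfg.fc_mode,
                "n_candidates": int(len(cand)),
                "precision": report.precision,
                "recall": report.recall,
            }
        )
    return pd.DataFrame(rows)


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write evaluation.tsv; undefined ratios serialized as 'NA'."""
    frame = report.to_frame()
    frame["value"] = [
        "NA" if isinstance(v, float) and np.isnan(v) else v for v in frame["value"]
    ]
    frame.to_csv(path, sep="\t", index=False)


def write_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    """Write sweep.tsv; undefined ratios serialized as 'NA'."""
    out = sweep.copy()
    for col in ("precision", "recall"):
        out[col] = ["NA" if np.isnan(v) else f"{v:.6f}" for v in out[col]]
    out.to_csv(path, sep="\t", index=False)
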