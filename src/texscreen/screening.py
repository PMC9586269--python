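"""Tissue-exclusive expression screen.

Every gene's RPKM profile across libraries is compared with an indicator
template that is 1 in the target-tissue libraries and 0 elsewhere. A gene
is a candidate when all three conjunctive filters pass:

* Pearson correlation of the profile with the template, r >= r_min;
* mean RPKM over the target libraries >= rpkm_min;
* fold change of target expression over the other libraries >= fc_min.

All thresholds are inclusive. The fold change is computed against the
maximum of the non-target libraries by default (the most stringent
reading of "target versus other samples"); the mean is available as an
alternative. A pseudocount epsilon (in RPKM units) keeps the ratio finite
for perfectly exclusive genes; with epsilon = 0 a zero denominator yields
+infinity.

Genes whose profile has zero variance (e.g. constitutively expressed or
all-zero genes) have an undefined correlation; they fail the r filter
rather than raising, since a flat profile cannot be tissue-exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ParameterError, SchemaError, TexscreenError


class DegenerateTemplateError(TexscreenError):
    """All libraries are target (or none are): the template has no contrast."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screen; defaults are the study's published cutoffs."""

    r_min: float = 0.99
    rpkm_min: float = 10.0
    fc_min: float = 5.0
    epsilon: float = 0.1
    fc_mode: str = "max"  # denominator over non-target libraries: "max" or "mean"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_min <= 1.0:
            raise ParameterError(f"r_min must lie in [-1, 1], got {self.r_min}")
        if self.rpkm_min < 0:
            raise ParameterError(f"rpkm_min must be >= 0, got {self.rpkm_min}")
        if self.fc_min < 1:
            raise ParameterError(f"fc_min must be >= 1, got {self.fc_min}")
        if self.epsilon < 0:
            raise ParameterError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.fc_mode not in ("max", "mean"):
            raise ParameterError(f"fc_mode must be 'max' or 'mean', got {self.fc_mode!r}")


def template_vector(samples: pd.DataFrame) -> np.ndarray:
    """Indicator template over libraries: 1 for target, 0 otherwise."""
    t = samples["is_target"].to_numpy(dtype=float)
    if len(t) < 2 or t.sum() == 0 or t.sum() == len(t):
        raise DegenerateTemplateError(
            "template needs at least one target and one non-target library; "
            f"got {int(t.sum())} target of {len(t)} libraries"
        )
    return t


def template_correlation(profile: np.ndarray, template: np.ndarray) -> float | None:
    """Sample Pearson correlation of a profile with the template.

    Returns None (undefined) when either vector has zero variance.
    """
    profile = np.asarray(profile, dtype=float)
    template = np.asarray(template, dtype=float)
    if profile.shape != template.shape:
        raise SchemaError(
            f"profile length {profile.shape} does not match template {template.shape}"
        )
    if profile.size < 2:
        raise SchemaError("correlation requires at least two libraries")
    dx = profile - profile.mean()
    dt = template - template.mean()
    ssx = float(dx @ dx)
    sst = float(dt @ dt)
    if ssx == 0.0 or sst == 0.0:
        return None
    return float(dx @ dt) / math.sqrt(ssx * sst)


def fold_change(
    profile: np.ndarray,
    target_mask: np.ndarray,
    epsilon: float = 0.1,
    mode: str = "max",
) -> float:
    """Target-over-others expression ratio.

    FC = (mean target RPKM + eps) / (agg non-target RPKM + eps), where agg
    is max (default) or mean. With eps = 0 and a zero denominator the
    result is +infinity.
    """
    profile = np.asarray(profile, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    if profile.shape != target_mask.shape:
        raise SchemaError("profile and target mask lengths differ")
    if not target_mask.any() or target_mask.all():
        raise DegenerateTemplateError("fold change needs target and non-target entries")
    num = float(profile[target_mask].mean()) + epsilon
    others = profile[~target_mask]
    denom = float(others.max() if mode == "max" else others.mean()) + epsilon
    if denom == 0.0:
        return math.inf if num > 0 else math.nan
    return num / denom


def screen(expr: ExpressionMatrix, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Apply the three-filter screen to every gene.

    Returns one record per gene with columns ``r`` (NaN when undefined),
    ``rpkm_target``, ``fold_change`` (may be +inf), the per-filter booleans
    and ``is_candidate``. Records are sorted by (is_candidate desc, r desc,
    fold_change desc, gene_id asc); undefined r sorts after any defined r.
    """
    config = config or ScreenConfig()
    template = template_vector(expr.samples)
    target_mask = template.astype(bool)

    X = expr.values.to_numpy(dtype=float)
    dt = template - template.mean()
    sst = float(dt @ dt)
    dx = X - X.mean(axis=1, keepdims=True)
    ssx = np.einsum("ij,ij->i", dx, dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dx @ dt) / np.sqrt(ssx * sst)
    r[ssx == 0.0] = np.nan

    rpkm_target = X[:, target_mask].mean(axis=1)
    others = X[:, ~target_mask]
    agg = others.max(axis=1) if config.fc_mode == "max" else others.mean(axis=1)
    num = rpkm_target + config.epsilon
    denom = agg + config.epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(denom == 0.0, np.where(num > 0.0, np.inf, np.nan), num / denom)

    pass_r = ~np.isnan(r) & (r >= config.r_min)
    pass_rpkm = rpkm_target >= config.rpkm_min
    pass_fc = ~np.isnan(fc) & (fc >= config.fc_min)
    is_candidate = pass_r & pass_rpkm & pass_fc

    records = pd.DataFrame(
        {
            "r": r,
            "rpkm_target": rpkm_target,
            "fold_change": fc,
            "pass_r": pass_r,
            "pass_rpkm": pass_rpkm,
            "pass_fc": pass_fc,
            "is_candidate": is_candidate,
        },
        index=expr.values.index.copy(),
    )
    records.index.name = "gene_id"
    # deterministic order: candidates first, then r, then FC, then gene_id
    records = records.assign(
        _r_key=records["r"].fillna(-2.0), _fc_key=records["fold_change"].fillna(-1.0)
    ).sort_values(
        by=["is_candidate", "_r_key", "_fc_key", "gene_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).drop(columns=["_r_key", "_fc_key"])
    return records


def candidates(records: pd.DataFrame) -> pd.DataFrame:
    """The subset of screen records with is_candidate = True."""
    return records.loc[records["is_candidate"]]


def write_candidates(records: pd.DataFrame, path) -> None:
    """Serialize screen records; +inf as 'inf', undefined r as 'NA'."""
    out = records.copy()
    out["r"] = [("NA" if np.isnan(v) else f"{v:.6f}") for v in out["r"]]
    out["fold_change"] = [
        ("inf" if np.isinf(v) else ("NA" if np.isnan(v) else f"{v:.6f}"))
        for v in out["fold_change"]
    ]
    out["rpkm_target"] = [f"{v:.6f}" for v in out["rpkm_target"]]
    for col in ("pass_r", "pass_rpkm", "pass_fc", "is_candidate"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t")


def read_candidates(path) -> pd.DataFrame:
    """Load a candidates.tsv written by :func:`write_candidates`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index("gene_id")
    df["r"] = pd.to_numeric(df["r"].replace("NA", np.nan))
    df["fold_change"] = pd.to_numeric(df["fold_change"].replace({"inf": np.inf, "NA": np.nan}))
    df["rpkm_target"] = pd.to_numeric(df["rpkm_target"])
    for col in ("pass_r", "pass_rpkm", "pass_fc", "is_candidate"):
        df[col] = df[col].astype(int).astype(bool)
    return df
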