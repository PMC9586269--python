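"""Brute-force reference implementation of the screen, used as a test oracle.

Deliberately independent of texscreen.screening: Pearson via
scipy.stats.pearsonr, fold change and the filters via explicit per-gene
Python loops.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats


def brute_force_screen(
    values: np.ndarray,
    gene_ids: list[str],
    is_target: list[bool],
    r_min: float = 0.99,
    rpkm_min: float = 10.0,
    fc_min: float = 5.0,
    epsilon: float = 0.1,
    fc_mode: str = "max",
) -> dict[str, dict]:
    """Per-gene screening outcome computed from first principles."""
    template = [1.0 if t else 0.0 for t in is_target]
    out: dict[str, dict] = {}
    for g, gene in enumerate(gene_ids):
        profile = [float(v) for v in values[g]]
        # Pearson; undefined when either vector is constant
        if len(set(profile)) == 1:
            r = None
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(stats.pearsonr(profile, template).statistic)
        target_vals = [v for v, t in zip(profile, is_target) if t]
        other_vals = [v for v, t in zip(profile, is_target) if not t]
        rpkm_target = sum(target_vals) / len(target_vals)
        num = rpkm_target + epsilon
        denom = (max(other_vals) if fc_mode == "max" else sum(other_vals) / len(other_vals)) + epsilon
        if denom == 0.0:
            fc = math.inf if num > 0 else math.nan
        else:
            fc = num / denom
        pass_r = r is not None and r >= r_min
        pass_rpkm = rpkm_target >= rpkm_min
        pass_fc = not math.isnan(fc) and fc >= fc_min
        out[gene] = {
            "r": r,
            "rpkm_target": rpkm_target,
            "fold_change": fc,
            "pass_r": pass_r,
            "pass_rpkm": pass_rpkm,
            "pass_fc": pass_fc,
            "is_candidate": pass_r and pass_rpkm and pass_fc,
        }
    return out


def random_expression_matrix(rng: np.random.Generator) -> tuple[np.ndarray, list[str], list[bool]]:
    """A small random RPKM-like matrix with awkward rows mixed in.

    Includes all-zero rows, constant rows, and sparse rows so that the
    undefined-correlation and infinite-fold-change paths are exercised.
    """
    n_genes = int(rng.integers(1, 51))
    n_libs = int(rng.integers(2, 7))
    n_target = int(rng.integers(1, n_libs))
    is_target = [i < n_target for i in range(n_libs)]
    perm = rng.permutation(n_libs)
    is_target = [is_target[i] for i in perm]
    vals = rng.gamma(shape=0.7, scale=30.0, size=(n_genes, n_libs))
    vals[rng.random(vals.shape) < 0.35] = 0.0
    for g in range(n_genes):
        u = rng.random()
        if u < 0.1:
            vals[g] = 0.0
        elif u < 0.2:
            vals[g] = float(rng.integers(0, 40))
        elif u < 0.35:  # near-exclusive pattern
            vals[g] = 0.0
            vals[g, np.array(is_target)] = float(rng.integers(1, 300))
    return vals, [f"g{i}" for i in range(n_genes)], is_target
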