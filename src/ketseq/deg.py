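"""Differentially expressed gene (DEG) calling with the variable
expression-ratio threshold.

A gene is a DEG when its BH-adjusted p-value is below ``p_cut`` AND its
maximum pseudocount expression ratio across the three major pairwise
comparisons (control vs 10 h, 10 h vs recovery, control vs 1 h) meets a
fold-change threshold that depends on expression level:

    threshold(E) = c * 2**(1 - log10(E)) + 1

with E the largest group-mean expression (sFPKM role) across the
experiment's groups and c = 0.4, i.e. a 40% change is required at
E = 10 and the requirement relaxes toward 1 as expression grows.
Expression ratios use a pseudocount of 0.1 in numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdParams",
    "COMPARISONS",
    "expression_ratio",
    "max_expression_ratio",
    "ratio_threshold",
    "classify_degs",
    "summarize_direction",
]

#: The three major pairwise comparisons, as (numerator, denominator) groups.
COMPARISONS = (("10h", "Control"), ("10h", "Recovery"), ("1h", "Control"))


@dataclass(frozen=True)
class ThresholdParams:
    """Pseudocount, threshold coefficient and significance cutoff."""

    epsilon: float = 0.1
    c: float = 0.4
    p_cut: float = 0.01

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.c <= 0:
            raise ValueError("threshold coefficient c must be > 0")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0, 1)")


def expression_ratio(mean_num, mean_den, epsilon: float = 0.1):
    """Pseudocount expression ratio (mean_num + eps) / (mean_den + eps)."""
    num = np.asarray(mean_num, dtype=float)
    den = np.asarray(mean_den, dtype=float)
    if np.any(num < 0) or np.any(den < 0):
        raise ValueError("group means must be >= 0")
    if epsilon == 0 and np.any(den == 0):
        raise ValueError("zero denominator with zero pseudocount")
    out = (num + epsilon) / (den + epsilon)
    return float(out) if out.ndim == 0 else out


def max_expression_ratio(group_means, epsilon: float = 0.1):
    """Largest direction-free pairwise expression ratio and its comparison.

    ``group_means`` maps group name -> mean expression (a dict, Series or
    single DataFrame row).  For each available comparison the larger of the
    two directed ratios (>= 1) is computed; the maximum and its comparison
    label (e.g. ``"10h/Control"``) are returned.  Two-group (female)
    experiments use only control vs 10 h.
    """
    gm = dict(group_means)
    if "Control" not in gm or "10h" not in gm:
        raise ValueError("group means must include Control and 10h")
    best, label = -np.inf, None
    for a, b in COMPARISONS:
        if a not in gm or b not in gm:
            continue
        r = expression_ratio(gm[a], gm[b], epsilon)
        mag = max(r, 1.0 / r)
        if mag > best:
            best, label = mag, f"{a}/{b}"
    return best, label


def ratio_threshold(max_sfpkm, c: float = 0.4):
    """Minimum required max expression ratio at a given expression level."""
    e = np.asarray(max_sfpkm, dtype=float)
    if np.any(e <= 0):
        raise ValueError("max sFPKM must be > 0")
    out = c * 2.0 ** (1.0 - np.log10(e)) + 1.0
    return float(out) if out.ndim == 0 else out


def classify_degs(de: pd.DataFrame, params: ThresholdParams = ThresholdParams()) -> pd.DataFrame:
    """Apply the DEG definition to a per-experiment DE result.

    ``de`` is the output of :func:`ketseq.diffexpr.run_de` (``mean_<group>``
    columns plus ``adj_p``).  Returns a DataFrame indexed by gene with
    max_ER, the comparison achieving it, max_sfpkm, threshold, adj_p,
    direction_at_10h ("up"/"down") and the passes flag.
    """
    groups = [c[len("mean_"):] for c in de.columns if c.startswith("mean_")]
    if "Control" not in groups or "10h" not in groups:
        raise ValueError("DE result must include Control and 10h group means")
    means = {g: de[f"mean_{g}"].to_numpy(dtype=float) for g in groups}

    eps = params.epsilon
    mags, labels = None, None
    for a, b in COMPARISONS:
        if a not in means or b not in means:
            continue
        r = expression_ratio(means[a], means[b], eps)
        mag = np.maximum(r, 1.0 / r)
        lab = f"{a}/{b}"
        if mags is None:
            mags, labels = mag, np.full(len(mag), lab, dtype=object)
            dir_of_max = np.where(r >= 1.0, "up", "down").astype(object)
        else:
            better = mag > mags
            labels = np.where(better, lab, labels)
            dir_of_max = np.where(better, np.where(r >= 1.0, "up", "down"), dir_of_max)
            mags = np.maximum(mag, mags)

    max_sfpkm = np.maximum.reduce([means[g] for g in groups])
    thr = np.where(max_sfpkm > 0, ratio_threshold(np.maximum(max_sfpkm, 1e-300), params.c), np.inf)

    er_10h = expression_ratio(means["10h"], means["Control"], eps)
    direction = np.where(er_10h > 1.0, "up", np.where(er_10h < 1.0, "down", dir_of_max))

    adj_p = de["adj_p"].to_numpy(dtype=float)
    passes = (adj_p < params.p_cut) & (mags >= thr)
    return pd.DataFrame(
        {
            "max_ER": mags,
            "comparison": labels,
            "max_sfpkm": max_sfpkm,
            "threshold": thr,
            "adj_p": adj_p,
            "direction_at_10h": direction,
            "passes": passes,
        },
        index=de.index,
    )


def summarize_direction(degs: pd.DataFrame) -> dict:
    """Counts and whole-percent shares of up / down DEGs.

    Accepts either a :func:`classify_degs` table (rows with ``passes`` are
    counted) or a mapping/DataFrame with explicit ``up``/``down`` counts.
    """
    if isinstance(degs, pd.DataFrame) and "passes" in degs.columns:
        sub = degs.loc[degs["passes"]]
        n_up = int((sub["direction_at_10h"] == "up").sum())
        n_down = int((sub["direction_at_10h"] == "down").sum())
    elif "up" in degs:
        n_up, n_down = int(degs["up"]), int(degs["down"])
    else:
        n_up, n_down = int(degs["n_up"]), int(degs["n_down"])
    total = n_up + n_down
    if total == 0:
        raise ValueError("no DEGs to summarize")
    return {
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": int(round(100.0 * n_up / total)),
        "pct_down": int(round(100.0 * n_down / total)),
    }
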