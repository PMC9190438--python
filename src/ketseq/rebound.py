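"""Post-infusion transcriptional rebound (overshoot) quantification.

At 24 h after the end of a 10 h infusion many regulated genes do not
simply return to baseline but overshoot in the opposite direction.  Genes
are placed in the four quadrants of the (log2 10h/control, log2
recovery/control) plane; the hatched quadrants — where the two ratios
disagree in sign — are the rebound quadrants.  The dataset-level trend is
tested with an exact binomial sign test (this package's choice of test;
labeled as such in output), and the rebound magnitude is summarized as
the median |log2 recovery ratio| / |log2 10 h ratio| among flagged genes
moving in the experiment's dominant 10 h direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .deg import expression_ratio, ratio_threshold

__all__ = [
    "rebound_table",
    "rebound_magnitude",
    "rebound_sign_test",
    "plot_rebound",
]


def rebound_table(de: pd.DataFrame, epsilon: float = 0.1, degs: pd.DataFrame = None) -> pd.DataFrame:
    """Quadrant classification of 10 h vs recovery log ratios.

    ``de`` is a per-experiment DE result with ``mean_<group>`` columns for
    all four groups; ``degs`` (optional) restricts rows to genes whose
    ``passes`` flag is set.  Returns a DataFrame with log2_ER_10h,
    log2_ER_rec, quadrant and rebound_flag.  Genes with a zero log ratio
    are assigned "persist" (no evidence of rebound).
    """
    for g in ("Control", "10h", "Recovery"):
        if f"mean_{g}" not in de.columns:
            raise ValueError(f"missing {g} group means (4-group experiment required)")
    sub = de if degs is None else de.loc[degs.loc[degs["passes"]].index]
    l10 = np.log2(expression_ratio(sub["mean_10h"], sub["mean_Control"], epsilon))
    lrec = np.log2(expression_ratio(sub["mean_Recovery"], sub["mean_Control"], epsilon))
    rebound = (np.sign(l10) != np.sign(lrec)) & (np.sign(l10) != 0) & (np.sign(lrec) != 0)
    quadrant = np.where(
        l10 > 0,
        np.where(rebound, "up-rebound", "up-persist"),
        np.where(rebound, "down-rebound", "down-persist"),
    )
    quadrant = np.where(l10 == 0, "up-persist", quadrant)

    # is the recovery excursion itself a thresholded regulation event?
    mean_cols = [c for c in sub.columns if c.startswith("mean_")]
    max_sfpkm = sub[mean_cols].max(axis=1).to_numpy(dtype=float)
    rec_mag = np.maximum(2.0**lrec, 2.0**-lrec)
    thr = ratio_threshold(np.maximum(max_sfpkm, 1e-300))
    strong = np.asarray(rebound) & (np.asarray(rec_mag) >= thr)
    return pd.DataFrame(
        {
            "log2_ER_10h": np.asarray(l10),
            "log2_ER_rec": np.asarray(lrec),
            "quadrant": quadrant,
            "rebound_flag": np.asarray(rebound),
            "strong_rebound": strong,
        },
        index=sub.index,
    )


def dominant_direction(records: pd.DataFrame) -> str:
    """Direction ("up"/"down") of the majority of genes at 10 h."""
    n_up = int((records["log2_ER_10h"] > 0).sum())
    n_down = int((records["log2_ER_10h"] < 0).sum())
    return "up" if n_up >= n_down else "down"


def rebound_magnitude(
    records: pd.DataFrame, direction: str = None, strong_only: bool = True
) -> float:
    """Median |log2 rec| / |log2 10h| among rebounding genes.

    Restricted to genes moving in ``direction`` at 10 h (default: the
    experiment's dominant direction).  By default only strongly regulated
    rebounds count — genes whose recovery excursion itself meets the
    variable expression-ratio threshold — so that sign flips within the
    noise band of fully recovered genes do not dilute the estimate; pass
    ``strong_only=False`` for the bare median over all flagged genes.
    """
    if direction is None:
        direction = dominant_direction(records)
    flag = records["strong_rebound" if strong_only else "rebound_flag"]
    sign = 1.0 if direction == "up" else -1.0
    sel = records.loc[flag & (sign * records["log2_ER_10h"] > 0)]
    if sel.empty:
        raise ValueError("no flagged rebound genes in the requested direction")
    return float(np.median(np.abs(sel["log2_ER_rec"]) / np.abs(sel["log2_ER_10h"])))


def rebound_sign_test(records: pd.DataFrame):
    """Exact two-sided binomial test of the rebound trend.

    Returns ``(n_rebound, n_total, p)`` testing the number of flagged
    genes among all genes with both ratios non-zero against probability
    one half.
    """
    defined = (records["log2_ER_10h"] != 0) & (records["log2_ER_rec"] != 0)
    n_total = int(defined.sum())
    n_rebound = int(records.loc[defined, "rebound_flag"].sum())
    if n_total < 1:
        raise ValueError("no genes with both ratios defined")
    p = float(stats.binomtest(n_rebound, n_total, 0.5).pvalue)
    return n_rebound, n_total, p


def plot_rebound(records: pd.DataFrame, ax=None, title: str = None):
    """Scatter of log ratios with the rebound quadrants hatched."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lim = float(np.nanmax(np.abs(records[["log2_ER_10h", "log2_ER_rec"]].to_numpy()))) * 1.1 or 1.0
    for sx, sy in ((1, -1), (-1, 1)):
        ax.fill_between([0, sx * lim], 0, sy * lim, color="red", alpha=0.08, hatch="//")
    ax.scatter(records["log2_ER_10h"], records["log2_ER_rec"], s=8, alpha=0.6, c="k")
    ax.axhline(0, lw=0.8, c="gray")
    ax.axvline(0, lw=0.8, c="gray")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("log2 ER (10 h / control)")
    ax.set_ylabel("log2 ER (recovery / control)")
    if title:
        ax.set_title(title)
    return ax
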