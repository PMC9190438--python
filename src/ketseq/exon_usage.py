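"""Simplified differential exon-usage testing ("JunctionSeq-style
(simplified)").

Tests whether an exon's share of its gene's total expression differs
between two groups — isoform-selective regulation, as opposed to overall
induction of the gene.  Usage proportions get a 0.5 pseudocount, are
logit-transformed, and compared between groups with the moderated-t
machinery of :mod:`ketseq.diffexpr` on unit weights; BH adjustment runs
across all tested exons.  The generalized-linear framework of the
junction-level tools is deliberately not reproduced; only the key
property is kept: the statistic responds to relative usage, not to
total-expression changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import fit_moderated, group_design

__all__ = ["usage_proportion", "differential_usage"]


def usage_proportion(exon_count, gene_total, pseudocount: float = 0.5):
    """Pseudocounted exon usage (exon + 0.5) / (total + 1)."""
    e = np.asarray(exon_count, dtype=float)
    t = np.asarray(gene_total, dtype=float)
    out = (e + pseudocount) / (t + 2.0 * pseudocount)
    return float(out) if out.ndim == 0 else out


def differential_usage(
    counts: pd.DataFrame, groups: pd.Series, d0: float = None
) -> pd.DataFrame:
    """Two-group moderated test of logit exon usage.

    ``counts`` is indexed by (gene, exon) with one column per sample;
    ``groups`` labels each sample with one of exactly two groups.  Genes
    with a single exon are skipped with a notice column.  Returns a
    DataFrame indexed by (gene, exon) with per-group usage proportions,
    the usage log-odds difference, moderated statistic, nominal p and BH
    adjusted p across all tested exons.
    """
    if counts.isna().any().any():
        raise ValueError("exon counts contain missing values")
    groups = groups.reindex(counts.columns)
    levels = sorted(groups.unique())
    if "Control" in levels:  # control is the baseline of the log-odds difference
        levels.remove("Control")
        levels.insert(0, "Control")
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if (groups.value_counts() < 2).any():
        raise ValueError("at least 2 samples per group required")

    totals = counts.groupby(level="gene").transform("sum")
    usage = usage_proportion(counts.to_numpy(), totals.to_numpy())
    logit = pd.DataFrame(
        np.log(usage / (1.0 - usage)), index=counts.index, columns=counts.columns
    )

    n_exons = counts.groupby(level="gene").size()
    multi = counts.index.get_level_values("gene").map(n_exons) > 1
    tested = logit.loc[multi]
    skipped = counts.index[~multi]

    design = group_design(groups, levels=levels)
    res = fit_moderated(tested, pd.DataFrame(np.ones_like(tested), index=tested.index,
                                             columns=tested.columns), design, d0=d0)

    out = pd.DataFrame(index=tested.index)
    for lv in levels:
        cols = list(groups.index[groups == lv])
        out[f"usage_{lv}"] = pd.DataFrame(usage, index=counts.index,
                                          columns=counts.columns).loc[multi, cols].mean(axis=1)
        out[f"logit_{lv}"] = res[f"coef_{lv}"]
    out["log_odds_diff"] = out[f"logit_{levels[1]}"] - out[f"logit_{levels[0]}"]
    out["F"] = res["F"]
    out["p"] = res["p"]
    out["adj_p"] = res["adj_p"]
    out.attrs["skipped_single_exon"] = list(skipped)
    if len(skipped):
        out.attrs["notice"] = f"skipped {len(skipped)} single-exon gene entries"
    return out
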