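"""Cross-dataset consensus: genes meeting the DEG threshold in at least
three of the five statistically tested experiments.

Five experiments carry statistics (three male regions, female hippocampus
and amygdala); the sixth (female frontal cortex, two animals per group)
contributes expression ratios but no passes.  Qualifying genes are checked
for direction concordance, ranked by the average signed log2 max ratio
across the six datasets, and grouped into pharmacology-relevant category
panels (receptors use a lower expression floor because receptor genes are
often lowly expressed).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "consensus_filter",
    "direction_concordance",
    "rank_and_select",
    "category_panels",
]


def _signed_log2(max_er: pd.Series, direction: pd.Series) -> pd.Series:
    sign = np.where(direction == "down", -1.0, 1.0)
    return pd.Series(sign * np.log2(max_er.to_numpy(dtype=float)), index=max_er.index)


def consensus_filter(
    deg_tables: dict,
    ratio_only: dict = None,
    min_pass: int = 3,
    min_max_sfpkm: float = 1.0,
) -> pd.DataFrame:
    """Genes passing the DEG threshold in >= ``min_pass`` experiments.

    ``deg_tables`` maps experiment name -> :func:`ketseq.deg.classify_degs`
    table (these experiments contribute passes); ``ratio_only`` maps name
    -> table contributing ratios but never passes.  Genes must reach
    ``min_max_sfpkm`` in at least one dataset.  Returns one row per
    qualifying gene with n_pass, per-dataset max_ER / direction, the
    average signed ratio across all datasets (geometric-mean scale) and a
    concordance flag.
    """
    all_tables = dict(deg_tables)
    for name, tab in (ratio_only or {}).items():
        if name in all_tables:
            raise ValueError(f"duplicate experiment name {name!r}")
        all_tables[name] = tab

    genes = None
    for tab in all_tables.values():
        genes = tab.index if genes is None else genes.union(tab.index)

    n_pass = pd.Series(0, index=genes)
    for tab in deg_tables.values():
        n_pass = n_pass.add(tab["passes"].reindex(genes, fill_value=False).astype(int), fill_value=0)
    max_sfpkm = pd.concat(
        [t["max_sfpkm"].reindex(genes) for t in all_tables.values()], axis=1
    ).max(axis=1)

    keep = (n_pass >= min_pass) & (max_sfpkm >= min_max_sfpkm)
    out = pd.DataFrame(index=genes[keep.to_numpy()])
    out["n_pass"] = n_pass[keep]
    out["max_sfpkm"] = max_sfpkm[keep]

    signed = []
    for name, tab in all_tables.items():
        sub = tab.reindex(out.index)
        out[f"max_ER_{name}"] = sub["max_ER"]
        out[f"direction_{name}"] = sub["direction_at_10h"]
        signed.append(_signed_log2(sub["max_ER"].fillna(1.0), sub["direction_at_10h"]))
    avg_signed = pd.concat(signed, axis=1).mean(axis=1)
    out["avg_log2_ER"] = avg_signed
    out["avg_max_ER"] = 2.0 ** avg_signed.abs()
    out["avg_direction"] = np.where(avg_signed >= 0, "up", "down")

    dir_cols = [c for c in out.columns if c.startswith("direction_")]
    dirs = out[dir_cols]
    out["concordant"] = dirs.apply(lambda r: r.dropna().nunique() <= 1, axis=1)
    return out.sort_values("avg_log2_ER", ascending=False)


def direction_concordance(records: pd.DataFrame, min_sfpkm: float = 0.0):
    """Per-gene direction concordance across expressed datasets.

    Returns ``(n_concordant, exceptions)`` where exceptions lists genes
    whose direction differs between datasets (considering only datasets
    where the gene's max sFPKM is above ``min_sfpkm`` when per-dataset
    expression columns are present).
    """
    if records.empty:
        return 0, []
    dir_cols = [c for c in records.columns if c.startswith("direction_")]
    exceptions = []
    n_conc = 0
    for gene, row in records.iterrows():
        dirs = row[dir_cols].dropna()
        if min_sfpkm > 0:
            expressed = []
            for c in dirs.index:
                name = c[len("direction_"):]
                er_col = f"max_ER_{name}"
                if er_col in records.columns and not np.isnan(row[er_col]):
                    expressed.append(c)
            dirs = dirs[expressed] if expressed else dirs
        if dirs.nunique() <= 1:
            n_conc += 1
        else:
            exceptions.append(gene)
    return n_conc, exceptions


def rank_and_select(
    records: pd.DataFrame, n_up: int = 10, n_down: int = 5, min_sfpkm: float = 5.0
):
    """Top increasing and decreasing consensus genes above an expression floor.

    Sorted by the average signed log2 ratio: descending for the increasing
    panel, ascending for the decreasing panel (most strongly decreasing
    first).  Returns ``(up_panel, down_panel)``.
    """
    sub = records.loc[records["max_sfpkm"] >= min_sfpkm]
    up = sub.loc[sub["avg_log2_ER"] > 0].sort_values("avg_log2_ER", ascending=False)
    down = sub.loc[sub["avg_log2_ER"] < 0].sort_values("avg_log2_ER", ascending=True)
    if len(up) < n_up:
        warnings.warn(f"only {len(up)} increasing genes available (requested {n_up})")
    if len(down) < n_down:
        warnings.warn(f"only {len(down)} decreasing genes available (requested {n_down})")
    return up.head(n_up), down.head(n_down)


def category_panels(
    records: pd.DataFrame,
    categories: pd.DataFrame,
    receptor_floor: float = 1.0,
    global_floor: float = 5.0,
) -> dict:
    """Per-category consensus tables (receptor, heat_shock, ion_channel, ...).

    ``categories`` has columns ``gene`` and ``category``; a gene may carry
    several categories.  The receptor panel uses the relaxed expression
    floor; all other categories use the global floor.
    """
    panels = {}
    for cat, sub in categories.groupby("category"):
        floor = receptor_floor if cat == "receptor" else global_floor
        genes = [g for g in sub["gene"] if g in records.index]
        tab = records.loc[genes]
        panels[cat] = tab.loc[tab["max_sfpkm"] >= floor].sort_values(
            "avg_log2_ER", ascending=False
        )
    return panels
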