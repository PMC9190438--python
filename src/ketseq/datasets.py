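"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_published_group_means",
    "load_published_deg_counts",
    "load_gene_categories",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ketseq.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_published_group_means() -> pd.DataFrame:
    """Published group-mean expression values (sFPKM) for the top regulated
    genes in each male brain region, with the printed 10h/control
    pseudocount expression ratios and adjusted p-values — the package's
    worked-example fixture."""
    return _read("published_group_means.tsv")


def load_published_deg_counts() -> pd.DataFrame:
    """Published DEG counts (increasing/decreasing) per region x sex."""
    return _read("published_deg_counts.tsv")


def load_gene_categories() -> pd.DataFrame:
    """Editable gene -> category annotation for consensus category panels."""
    return _read("gene_categories.tsv")
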