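"""Male/female concordance at 10 h, discordance ranking, cell-type
attribution and the sex x treatment interaction test.

Expression values at 10 h are scaled to sex-specific average controls so
that both sexes are compared on normalized expression ratios; rows are
Ward-clustered for heatmap display; the most sex-discordant genes are
ranked by the absolute difference of log2 expression ratios and attributed
to brain cell types with a reference expression table; and a formal
interaction test (Sex x Ketamine) re-uses the moderated machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .diffexpr import fit_moderated, voom_weights
from .io import CountMatrix

__all__ = [
    "scale_to_sex_controls",
    "ward_cluster",
    "discordance_rank",
    "celltype_attribute",
    "interaction_test",
]


def scale_to_sex_controls(expr, epsilon: float = 0.1) -> pd.DataFrame:
    """Scale each sex's 10 h samples to that sex's average control.

    ``expr`` is an :class:`~ketseq.io.ExpressionMatrix` restricted to one
    region.  Every 10 h sample column is divided by (control mean of its
    sex + epsilon).  Returns the normalized-ratio matrix (genes x 10 h
    samples).
    """
    out = {}
    for sex in ("male", "female"):
        ctrl = expr.samples_of(group="Control", sex=sex)
        tens = expr.samples_of(group="10h", sex=sex)
        if not ctrl or not tens:
            continue
        denom = expr.values[ctrl].mean(axis=1) + epsilon
        for sid in tens:
            out[sid] = expr.values[sid] / denom
    if not out:
        raise ValueError("no control/10h samples for either sex")
    return pd.DataFrame(out)


def ward_cluster(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Ward-linkage agglomerative clustering of row-standardized rows.

    Euclidean distances on z-scored rows, Ward's minimum-variance linkage
    (the ward.D2 convention: squared distances inside the criterion).
    Returns integer labels 1..k indexed like the input rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValueError("more clusters than rows")
    x = np.asarray(matrix, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    if matrix.shape[0] == 1:
        return pd.Series([1], index=matrix.index, name="cluster")
    labels = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")


def discordance_rank(
    male_er: pd.Series, female_er: pd.Series, n_top: int = 30
) -> pd.DataFrame:
    """Top sex-discordant genes by |log2 ER_male - log2 ER_female|.

    Ratios must be positive (pseudocount ratios).  Ties are broken by gene
    id.  Returns the top ``n_top`` rows, highest score first.
    """
    common = male_er.index.intersection(female_er.index)
    lm = np.log2(male_er.loc[common].to_numpy(dtype=float))
    lf = np.log2(female_er.loc[common].to_numpy(dtype=float))
    df = pd.DataFrame(
        {"log2_ER_male": lm, "log2_ER_female": lf, "score": np.abs(lm - lf)},
        index=common,
    )
    df = df.sort_values(["score"], ascending=False, kind="stable")
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["score"].to_numpy()))]
    return df.head(n_top)


def celltype_attribute(
    genes, reference: pd.DataFrame, pseudocount: float = 0.1, min_enrichment: float = 2.0
) -> pd.DataFrame:
    """Attribute genes to the cell type where they are most enriched.

    Enrichment is (max column + pseudocount) / (mean of other columns +
    pseudocount); genes below ``min_enrichment`` or absent from the
    reference are "unassigned".
    """
    rows = []
    cols = list(reference.columns)
    for g in genes:
        if g not in reference.index:
            rows.append((g, "unassigned", np.nan))
            continue
        v = reference.loc[g].to_numpy(dtype=float)
        j = int(np.argmax(v))
        others = np.delete(v, j)
        enrich = (v[j] + pseudocount) / (others.mean() + pseudocount)
        rows.append((g, cols[j] if enrich >= min_enrichment else "unassigned", float(enrich)))
    return pd.DataFrame(rows, columns=["gene", "cell_type", "enrichment"]).set_index("gene")


def interaction_test(counts: CountMatrix, region: str, span: float = 0.5) -> pd.DataFrame:
    """Moderated test of the Sex x Ketamine interaction in one region.

    Uses control and 10 h samples of both sexes; the full design has
    intercept, sex, treatment and interaction columns and the moderated F
    (1 numerator df) compares it against the no-interaction design, with
    BH adjustment across genes.
    """
    if counts.meta is None:
        raise ValueError("count matrix has no sample metadata")
    m = counts.meta
    sel = (m["region"] == region) & m["group"].isin(["Control", "10h"])
    sub_meta = m.loc[sel].reset_index(drop=True)
    if sub_meta["sex"].nunique() < 2:
        raise ValueError("both sexes required for the interaction test")
    ids = list(sub_meta["sample_id"])
    sub = CountMatrix(
        counts=counts.counts[ids],
        gene_lengths=counts.gene_lengths,
        library_sizes=counts.library_sizes[ids],
        meta=sub_meta,
    )
    sex = (sub_meta["sex"] == "male").to_numpy(dtype=float)
    ket = (sub_meta["group"] == "10h").to_numpy(dtype=float)
    full = pd.DataFrame(
        {"intercept": 1.0, "sex": sex, "ketamine": ket, "sex_x_ketamine": sex * ket}
    )
    reduced = full[["intercept", "sex", "ketamine"]]
    logcpm, w = voom_weights(sub, full, span=span)
    return fit_moderated(logcpm, w, full, reduced=reduced)
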