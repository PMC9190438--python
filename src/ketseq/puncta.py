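"""Statistics on multiplex fluorescent in situ hybridization puncta.

Downstream analysis of per-animal puncta intensity tables (segmentation
itself is out of scope): intensities on the 0-255 scale are binned per 10
levels into 26 bins (the final bin [250, 255] is truncated — the scale
does not divide evenly, a choice recorded in output headers), counts are
log-transformed and analyzed with a repeated-measures two-way mixed ANOVA
(between factor treatment, within factor intensity bin, animal as the
repeated unit, Greenhouse-Geisser correction), with Holm-Sidak-adjusted
per-bin treatment contrasts.  Marker co-expression 2x2 tables are tested
with Pearson's chi-square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["BIN_EDGES", "bin_puncta", "binned_anova", "coexpression_test"]

#: Half-open bins [0,10), [10,20), ..., [240,250), plus truncated [250,255].
BIN_EDGES = np.array(list(range(0, 260, 10)) + [256], dtype=float)  # 0,10,...,250,256
N_BINS = 26


def bin_puncta(table: pd.DataFrame) -> pd.DataFrame:
    """Animal x bin puncta counts from a per-punctum intensity table.

    ``table`` has columns animal_id, treatment, intensity (integers
    0-255).  Returns a DataFrame indexed by animal_id with 26 bin columns
    ``bin00`` .. ``bin25`` plus the treatment label; row sums equal each
    animal's puncta count.
    """
    inten = table["intensity"].to_numpy()
    if np.any((inten < 0) | (inten > 255)):
        raise ValueError("intensities must lie in [0, 255]")
    rows = {}
    treatments = {}
    for (animal, treat), sub in table.groupby(["animal_id", "treatment"], sort=False):
        hist, _ = np.histogram(sub["intensity"].to_numpy(), bins=BIN_EDGES)
        rows[animal] = hist
        treatments[animal] = treat
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"bin{i:02d}" for i in range(N_BINS)]
    )
    out.insert(0, "treatment", pd.Series(treatments))
    return out


def binned_anova(binned: pd.DataFrame):
    """Repeated-measures two-way ANOVA on log-transformed binned counts.

    Between factor = treatment, within factor = intensity bin, each animal
    a repeated unit; counts are log10(count + 1).  Returns ``(anova,
    per_bin)``: the mixed-ANOVA table (treatment, bin, interaction rows;
    Greenhouse-Geisser-corrected p for within effects where applicable)
    and a per-bin DataFrame of treatment contrasts with Holm-Sidak
    adjusted p-values.
    """
    if binned["treatment"].nunique() != 2:
        raise ValueError("exactly two treatments required")
    if (binned["treatment"].value_counts() < 2).any():
        raise ValueError("each treatment needs at least 2 animals")

    bin_cols = [c for c in binned.columns if c.startswith("bin")]
    long = binned.reset_index(names="animal_id").melt(
        id_vars=["animal_id", "treatment"],
        value_vars=bin_cols,
        var_name="bin",
        value_name="count",
    )
    long["logcount"] = np.log10(long["count"].astype(float) + 1.0)

    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            aov = pg.mixed_anova(
                data=long,
                dv="logcount",
                within="bin",
                subject="animal_id",
                between="treatment",
                correction=True,
            )
    except (KeyError, ZeroDivisionError, ValueError):
        # degenerate input (zero residual variance): no evidence of any effect
        aov = pd.DataFrame(
            {
                "Source": ["treatment", "bin", "Interaction"],
                "F": [np.nan] * 3,
                "p_unc": [1.0] * 3,
                "note": "degenerate: zero residual variance",
            }
        )

    levels = sorted(binned["treatment"].unique())
    a = binned.loc[binned["treatment"] == levels[0], bin_cols].to_numpy(dtype=float)
    b = binned.loc[binned["treatment"] == levels[1], bin_cols].to_numpy(dtype=float)
    la, lb = np.log10(a + 1.0), np.log10(b + 1.0)
    raw = []
    for j in range(len(bin_cols)):
        if np.ptp(la[:, j]) == 0 and np.ptp(lb[:, j]) == 0 and la[:, j].mean() == lb[:, j].mean():
            raw.append(1.0)
        else:
            raw.append(float(stats.ttest_ind(la[:, j], lb[:, j]).pvalue))
    raw = np.nan_to_num(np.asarray(raw), nan=1.0)
    with np.errstate(divide="ignore"):
        adj = multipletests(raw, method="holm-sidak")[1]
    per_bin = pd.DataFrame(
        {
            "bin": bin_cols,
            f"mean_log_{levels[0]}": la.mean(axis=0),
            f"mean_log_{levels[1]}": lb.mean(axis=0),
            "p": raw,
            "adj_p": adj,
        }
    ).set_index("bin")
    return aov, per_bin


def coexpression_test(counts):
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    ``counts`` is a 2x2 array or DataFrame of co-positive / not counts for
    two conditions.  Returns ``(percent_co_positive, chi2, p)`` where the
    percentages are per condition row.
    """
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("a 2x2 contingency table is required")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    pct = 100.0 * tab[:, 0] / tab.sum(axis=1)
    if isinstance(counts, pd.DataFrame):
        pct = pd.Series(pct, index=counts.index, name="pct_co_positive")
    return pct, float(chi2), float(p)
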