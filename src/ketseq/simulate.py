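"""Synthetic data generator for the infusion time-course pipeline.

Emulates the study design the analysis assumes: three brain regions x two
sexes, four time groups (Control = un-infused, 1 h and 10 h of infusion,
Recovery = 24 h after a 10 h infusion), gene response classes driven by
first-order mRNA turnover (half-lives ~2.5-3 h), animal-level lognormal
variability and negative-binomial count noise.  Ground-truth labels are
returned for parameter-recovery tests.

Also generates the auxiliary fixtures the downstream modules consume: a
brain cell-type reference expression table, exon-level count tables for a
multi-exon gene, and ISH puncta intensity tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GROUPS, CountMatrix
from .kinetics import KineticGeneProfile, abundance_at, expression_ratio_at

__all__ = [
    "EXPERIMENTS",
    "STUDY_GROUP_SIZES",
    "GROUP_TIMES",
    "CELL_TYPES",
    "SimulationDesign",
    "make_profiles",
    "simulate_experiment",
    "make_celltype_reference",
    "make_exon_counts",
    "make_puncta_tables",
]

#: The six region x sex experiments of the study design.
EXPERIMENTS = (
    ("frontal_cortex", "male"),
    ("hippocampus", "male"),
    ("amygdala", "male"),
    ("frontal_cortex", "female"),
    ("hippocampus", "female"),
    ("amygdala", "female"),
)

#: Animals per (experiment, group) in the study design; females have only Control and 10 h.
STUDY_GROUP_SIZES = {
    ("frontal_cortex", "male"): {"Control": 7, "1h": 6, "10h": 6, "Recovery": 6},
    ("hippocampus", "male"): {"Control": 7, "1h": 5, "10h": 7, "Recovery": 6},
    ("amygdala", "male"): {"Control": 6, "1h": 6, "10h": 7, "Recovery": 6},
    ("frontal_cortex", "female"): {"Control": 2, "10h": 2},
    ("hippocampus", "female"): {"Control": 5, "10h": 5},
    ("amygdala", "female"): {"Control": 5, "10h": 5},
}

#: Sampling time in hours for each group (Recovery = 10 h infusion + 24 h).
GROUP_TIMES = {"Control": 0.0, "1h": 1.0, "10h": 10.0, "Recovery": 34.0}

CELL_TYPES = ("endothelial", "microglia", "oligodendrocyte", "astrocyte", "neuron")

#: Default gene-class mixture.
DEFAULT_CLASS_MIX = {
    "induced": 0.10,
    "suppressed": 0.10,
    "rebound_up": 0.05,
    "rebound_down": 0.05,
    "null": 0.70,
}


@dataclass
class SimulationDesign:
    """Design of a simulated infusion experiment set.

    ``library_size`` is the nominal total mapped fragments per sample used
    in the FPKM formula; ``nb_dispersion`` is the negative-binomial
    dispersion phi (variance = mu + phi * mu^2, 0 = Poisson);``bio_cv`` is
    the per-gene animal-level lognormal coefficient of variation.
    """

    experiments: tuple = EXPERIMENTS
    group_sizes: dict = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    sample_times: dict = field(default_factory=lambda: dict(GROUP_TIMES))
    n_genes: int = 2000
    gene_length_bp: np.ndarray = None
    library_size: float = 5e6
    nb_dispersion: float = 0.05
    bio_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.bio_cv < 0:
            raise ValueError("bio_cv must be >= 0")
        if any(t < 0 for t in self.sample_times.values()):
            raise ValueError("sample times must be >= 0")
        for exp in self.experiments:
            if exp not in self.group_sizes:
                raise ValueError(f"no group sizes for experiment {exp}")


def make_profiles(
    n_genes: int = 2000,
    seed: int = 0,
    class_mix: dict = None,
    half_life_range: tuple = (2.5, 3.0),
    log2_fold_range: tuple = (1.0, 3.0),
    rho: float = 0.5,
    tau_reb: float = 30.0,
    region_sex_multipliers: dict = None,
) -> list:
    """Draw ground-truth kinetic profiles for ``n_genes`` genes.

    Non-null genes get an infusion fold of 2**U(log2_fold_range) (inverted
    for suppressed classes); rebound classes additionally get the rebound
    fraction ``rho``.  Baseline abundances are lognormal (median ~5 FPKM),
    half-lives uniform over ``half_life_range``.
    """
    rng = np.random.default_rng(seed)
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    labels = list(mix)
    counts = [int(round(mix[c] * n_genes)) for c in labels]
    counts[-1] = n_genes - sum(counts[:-1])
    classes = np.repeat(labels, counts)
    rng.shuffle(classes)

    width = len(str(n_genes - 1))
    profiles = []
    for i, label in enumerate(classes):
        t_half = rng.uniform(*half_life_range)
        k = np.log(2.0) / t_half
        base = float(np.exp(rng.normal(np.log(5.0), 1.2)))
        lf = rng.uniform(*log2_fold_range)
        if label == "induced":
            f, r = 2.0 ** lf, 0.0
        elif label == "suppressed":
            f, r = 2.0 ** (-lf), 0.0
        elif label == "rebound_up":
            f, r = 2.0 ** lf, rho
        elif label == "rebound_down":
            f, r = 2.0 ** (-lf), rho
        elif label == "null":
            f, r = 1.0, 0.0
        else:
            raise ValueError(f"unknown gene class {label!r}")
        profiles.append(
            KineticGeneProfile(
                gene_id=f"g{i:0{width}d}",
                s0=base * k,
                t_half=t_half,
                f_mod=f,
                rho=r,
                tau_reb=tau_reb,
                class_label=label,
                region_sex_multipliers=dict(region_sex_multipliers.get(f"g{i:0{width}d}", {}))
                if region_sex_multipliers
                else {},
            )
        )
    return profiles


def simulate_experiment(design: SimulationDesign, profiles: list):
    """Simulate counts for every experiment in the design.

    Returns ``(CountMatrix, metadata, ground_truth)``.  The expected count
    for gene g in sample j is ``abundance * L_g * N_j / 1e9`` times a
    lognormal animal factor; counts are negative-binomial with dispersion
    phi (Poisson when phi = 0).  Metadata carries region, sex, group and
    animal id; ground truth has one row per gene x experiment with the
    class label and true expression ratios at each sample time.
    """
    if len(profiles) != design.n_genes:
        raise ValueError(
            f"profiles ({len(profiles)}) do not cover n_genes ({design.n_genes})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))

    if design.gene_length_bp is None:
        lengths = rng.integers(500, 10_000, size=design.n_genes)
    else:
        lengths = np.asarray(design.gene_length_bp, dtype=int)
        if lengths.shape != (design.n_genes,):
            raise ValueError("gene_length_bp must have one entry per gene")

    genes = [p.gene_id for p in profiles]
    meta_rows = []
    for region, sex in design.experiments:
        sizes = design.group_sizes[(region, sex)]
        for group in GROUPS:
            for a in range(sizes.get(group, 0)):
                sid = f"{region}_{sex}_{group}_{a}"
                meta_rows.append((sid, f"{region[:2]}{sex[0]}_{group}_{a}", region, sex, group))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "animal_id", "region", "sex", "group"]
    )

    n_samples = len(meta)
    times = meta["group"].map(design.sample_times).to_numpy(dtype=float)
    mu = np.empty((design.n_genes, n_samples))
    truth_rows = []
    for g, prof in enumerate(profiles):
        for region, sex in design.experiments:
            cols = (meta["region"] == region) & (meta["sex"] == sex)
            idx = np.flatnonzero(cols.to_numpy())
            mu[g, idx] = abundance_at(prof, times[idx], experiment=(region, sex))
            ratios = {
                grp: float(
                    expression_ratio_at(
                        prof, design.sample_times[grp], experiment=(region, sex)
                    )
                )
                for grp in design.group_sizes[(region, sex)]
            }
            truth_rows.append(
                {
                    "gene": prof.gene_id,
                    "region": region,
                    "sex": sex,
                    "class_label": prof.class_label,
                    "f_mod": prof.f_mod,
                    "effective_fold": prof.effective_fold((region, sex)),
                    "t_half": prof.t_half,
                    "rho": prof.rho,
                    "tau_reb": prof.tau_reb,
                    **{f"ratio_{g_}": r for g_, r in ratios.items()},
                }
            )
    truth = pd.DataFrame(truth_rows)

    # expected counts: FPKM -> fragments, times animal-level lognormal factor
    mu *= lengths[:, None] * design.library_size / 1e9
    if design.bio_cv > 0:
        sigma = np.sqrt(np.log1p(design.bio_cv**2))
        mu = mu * rng.lognormal(-0.5 * sigma**2, sigma, size=mu.shape)
    if design.nb_dispersion > 0:
        shape = 1.0 / design.nb_dispersion
        lam = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
    else:
        lam = mu
    counts = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=meta["sample_id"]),
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        library_sizes=pd.Series(design.library_size, index=meta["sample_id"], name="library_size"),
        meta=meta,
    )
    return cm, meta, truth


def make_celltype_reference(
    seed: int = 0, n_marker_genes: int = 20, n_nonspecific: int = 50
) -> pd.DataFrame:
    """Synthetic brain cell-type reference expression table.

    Returns a gene x cell-type DataFrame in which each marker gene is at
    least 10-fold enriched in its assigned type, plus non-specific genes
    with flat profiles.
    """
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for ct in CELL_TYPES:
        for i in range(n_marker_genes):
            base = rng.uniform(2.0, 8.0, size=len(CELL_TYPES))
            base[CELL_TYPES.index(ct)] = rng.uniform(150.0, 400.0)
            rows.append(base)
            names.append(f"{ct[:4]}_marker_{i:02d}")
    for i in range(n_nonspecific):
        level = rng.uniform(5.0, 50.0)
        rows.append(level * rng.uniform(0.9, 1.1, size=len(CELL_TYPES)))
        names.append(f"nonspecific_{i:02d}")
    return pd.DataFrame(rows, index=names, columns=list(CELL_TYPES))


def make_exon_counts(
    seed: int = 0,
    usage_shift: float = 0.0,
    n_control: int = 7,
    n_treated: int = 6,
    gene: str = "BdnfLike",
    exons: tuple = ("exon1", "exon2", "exon6", "exon9"),
    base_usage: tuple = (0.2, 0.2, 0.1, 0.5),
    total_mean: float = 500.0,
    induction_fold: float = 2.0,
):
    """Exon x sample counts for one multi-exon gene.

    The default encodes the pattern of an activity-induced neurotrophin
    gene: several alternative 5' exons all splicing onto one coding exon.
    ``usage_shift`` moves the first exon's relative usage in the treated
    group by that amount (others renormalized); gene totals follow the
    induction fold.  Returns ``(counts_df, groups)`` with counts indexed by
    (gene, exon) and a Series of group labels per sample.
    """
    if abs(sum(base_usage) - 1.0) > 1e-9:
        raise ValueError("base_usage must sum to 1")
    rng = np.random.default_rng(seed)
    p_ctrl = np.asarray(base_usage, dtype=float)
    p_trt = p_ctrl.copy()
    p_trt[0] += usage_shift
    if p_trt[0] <= 0 or p_trt[0] >= 1:
        raise ValueError("usage_shift pushes the target exon outside (0, 1)")
    p_trt[1:] *= (1.0 - p_trt[0]) / p_trt[1:].sum()

    cols, groups, mat = [], [], []
    for j in range(n_control):
        total = rng.poisson(total_mean)
        mat.append(rng.multinomial(total, p_ctrl))
        cols.append(f"control_{j}")
        groups.append("Control")
    for j in range(n_treated):
        total = rng.poisson(total_mean * induction_fold)
        mat.append(rng.multinomial(total, p_trt))
        cols.append(f"treated_{j}")
        groups.append("10h")
    counts = pd.DataFrame(
        np.array(mat).T,
        index=pd.MultiIndex.from_product([[gene], list(exons)], names=["gene", "exon"]),
        columns=cols,
    )
    return counts, pd.Series(groups, index=cols, name="group")


def make_puncta_tables(
    seed: int = 0,
    n_animals: int = 4,
    n_puncta_mean: float = 300.0,
    control_intensity: tuple = (80.0, 30.0),
    treated_intensity: tuple = (120.0, 30.0),
    coexpr_p: tuple = (0.5, 0.92),
    coexpr_n: int = 50,
):
    """Per-animal ISH puncta intensity tables and a co-expression 2x2 table.

    Puncta intensities are clipped-normal draws on the 0-255 scale with the
    given (mean, sd) per condition.  The co-expression table counts
    triple-marker co-positive vs not cells in each condition.  Returns
    ``(puncta_df, coexpr_df)`` where puncta_df has one row per punctum
    (animal_id, treatment, intensity).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, (m, s) in (("control", control_intensity), ("10h", treated_intensity)):
        for a in range(n_animals):
            n = rng.poisson(n_puncta_mean)
            vals = np.clip(np.round(rng.normal(m, s, size=n)), 0, 255).astype(int)
            rows.extend((f"{cond}_a{a}", cond, v) for v in vals)
    puncta = pd.DataFrame(rows, columns=["animal_id", "treatment", "intensity"])

    co = []
    for cond, p in zip(("control", "10h"), coexpr_p):
        k = int(rng.binomial(coexpr_n, p))
        co.append((k, coexpr_n - k))
    coexpr = pd.DataFrame(
        co, index=["control", "10h"], columns=["co_positive", "not_co_positive"]
    )
    return puncta, coexpr
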