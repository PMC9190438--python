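# Methods

## Kinetic model

Each gene's transcript abundance follows first-order turnover,

    dM/dt = s(t) − k·M,      k = ln 2 / T½,

with synthesis piecewise constant: s = f·s₀ during the infusion
(t ∈ [0, 10] h), s = s₀·f^(−ρ) during a post-infusion rebound window
(t ∈ (10, 10+τ_reb] h), and s = s₀ afterwards.  Controls are un-infused
and sit at the baseline steady state M₀ = s₀/k.  The solution is applied
piecewise in closed form; tests verify it against brute-force Euler
integration (dt = 10⁻³ h) to < 10⁻⁴ relative error.

The geometric rebound excursion (s₀·f^(−ρ) rather than an additive
reduction) is a deliberate choice: it keeps synthesis positive for any
effect size, and it makes the recovery-time log-scale excursion a fixed
fraction ρ of the main effect — log₂ M_rec/M₀ ≈ −ρ·log₂ f once the
excursion has converged — matching the observation that the rebound is
roughly half the 10 h effect regardless of the gene's fold change.  An
additive excursion of magnitude ρ·|f−1| fails both properties: it drives
synthesis negative when ρ·|f−1| > 1 and makes the log-scale rebound
fraction depend strongly on f.  For the excursion to be measurable at the
recovery sample (24 h after infusion end, ≈ 8–10 half-lives), the window
must still be open there; the default τ_reb = 30 h does that.  A shorter
window (e.g. 12 h) leaves ~2^(−12/T½) ≈ 5 % of the excursion by the
recovery sample, i.e. essentially full recovery.

Half-lives default to Uniform(2.5, 3) h.  Sampling times: control 0 h,
1 h, 10 h, recovery 34 h (10 h infusion + 24 h).

## Synthetic data

`simulate_experiment` reproduces the study design: six region × sex
experiments with the study's animal counts (male frontal cortex 7/6/6/6
across control/1 h/10 h/recovery, male hippocampus 7/5/7/6, male amygdala
6/6/7/6; females have control and 10 h only — 5/5 in hippocampus and
amygdala, 2/2 in frontal cortex).  Expected counts are
M(t)·L_g·N/10⁹ (abundance in FPKM units × gene length × nominal library
size), multiplied by one lognormal factor per gene × animal
(CV = `bio_cv`, default 0.2), with negative-binomial sampling of
dispersion φ (default 0.05; variance μ + φμ²; φ = 0 degenerates to
Poisson).  Gene classes default to 10 % induced, 10 % suppressed, 5 %
each rebound class, 70 % null, with log₂ folds Uniform(1, 3) (inverted
for suppression) and ρ = 0.5 for the rebound classes.  Baseline
abundances are lognormal with median ≈ 5 FPKM; gene lengths uniform
500–10 000 bp; the nominal library size defaults to 5×10⁶ fragments,
scaled to the simulated gene count so per-gene depths are comparable to a
~46 M-read library over a full transcriptome.  Per-gene effects can be
modulated per experiment through `region_sex_multipliers` (effective fold
1 + m·(f−1)), which is how shared vs region-private and male-only
responses are constructed in tests.

What the generator does **not** emulate: batch effects, correlated genes,
library-composition bias, gene-length-dependent dispersion, isoform
structure in the genome-wide matrix, or any real sequence content.
Passing property tests therefore demonstrate correctness and calibration
of the statistics under a clean generative model, not performance on real
libraries.

## Differential expression

Per experiment (region × sex), on raw counts: log₂-CPM with the
(count + 0.5)/(library + 1) convention; a lowess trend (span 0.5, single
pass) of √(residual SD) against average log-count; per-observation
weights = predicted trend value⁻⁴ clipped to [10⁻⁶, 10⁶]; gene-wise
weighted least squares on a cell-means group design; empirical-Bayes
moderation of residual variances, with (d₀, s₀²) estimated by the method
of moments on log s² — Var(log s²) exceeds trigamma(d_res/2) by
trigamma(d₀/2), inverted by Newton's method, with d₀ = ∞ (full shrinkage)
when the empirical spread is at or below the theoretical minimum.
Gene-level significance is the moderated F for equality of all group
means (denominator df d₀ + d_res; χ² limit when d₀ = ∞), BH-adjusted
across genes within the experiment.  Which contrast drives the original
datasets' adjusted p-values is not reconstructable, so numerical
agreement with their printed p-values is not expected; per-pair ratios
are reported descriptively.  `d0=0` gives exactly unmoderated WLS (used
as a test oracle), `d0=inf` full shrinkage.

Null-simulation calibration (2000 genes, 20 seeds): nominal p-values
uniform (KS < 0.05) and mean fraction of adjusted p < 0.01 at most 0.01.
Power: ≥ 80 % for |log₂ fold| ≥ 1 genes at male group sizes.

## DEG definition

Pseudocount expression ratio ER(a, b) = (mean_a + ε)/(mean_b + ε) with
ε = 0.1 sFPKM.  ε is not a printed constant: it was recovered by grid
search over [0, 1] minimizing the discrepancy between recomputed and
published 10 h/control ratio columns across all 120 published table rows
(0.1 is the clear minimizer; residual disagreement is ±0.01 rounding
noise because the published group means are 2-dp roundings).  The DEG
rule combines adjusted p < 0.01 with max ER over the three major
comparisons ≥ 0.4·2^(1−log₁₀ E) + 1, E being the largest group-mean
expression in the experiment.  The formula's parenthesization is fixed by
its own anchor (threshold 1.4 at E = 10, base-10 log); natural log or
other groupings contradict the anchor.  Direction at 10 h comes from the
10 h/control ratio; exact ties fall back to the direction of the
max-ER comparison.

## Rebound

For four-group experiments, DEGs are placed in quadrants of
(log₂ ER_10h, log₂ ER_rec); sign-discordant quadrants are rebound.  The
dataset-level trend is an exact two-sided binomial test of flagged vs
total (the original work reports only that the trend is significant; the
sign test is this package's choice and is labeled as such in output).
The rebound magnitude is the median of |log₂ ER_rec|/|log₂ ER_10h| over
rebounding genes moving in the experiment's dominant 10 h direction,
by default restricted to genes whose recovery excursion itself meets the
variable expression-ratio threshold ("strong" rebounds).  The
restriction matters: fully recovered genes flip sign within noise and
would otherwise pull the median far below the true rebound fraction; with
it, simulations at ρ = 0.5 recover 0.50 on average (range ≈ 0.43–0.70
over 20 seeds).  The unrestricted median is available via
`strong_only=False`.  Gene-level rebound significance is deliberately not
attempted.

## Sex and cell type

Ten-hour samples are scaled to sex-specific average controls (pseudocount
ε in the denominator), Ward-clustered (scipy's `ward` linkage on
Euclidean distances of row-standardized values — the ward.D2 convention;
cluster count default 4) for display, and ranked by the discordance score
|log₂ ER_male − log₂ ER_female| (the top 30 by default).  Cell-type
attribution assigns the argmax column of a reference expression table
(endothelial, microglia, oligodendrocyte, astrocyte, neuron; a synthetic
reference generator is included, and any table with the same TSV schema
can be loaded); enrichment is (max + 0.1)/(mean of others + 0.1) with
genes below 2 left unassigned — conservative, so flat genes stay out.
The formal Sex×Ketamine test reuses the moderated machinery with a
1-df interaction contrast on control + 10 h data of both sexes; on
simulations without sex effects it detects nothing, mirroring the
original negative result, and it has ≥ 50 % power for a male-only
fourfold induction at the study's group sizes.

## Consensus and panels

A consensus gene passes the DEG rule in ≥ 3 of the 5 experiments with
statistics and reaches max sFPKM ≥ 1 somewhere; the female frontal cortex
(2 animals/group) contributes expression ratios but never passes.  The
cross-dataset average is the mean of signed log₂ max-ER over all six
datasets (sign from the 10 h direction), converted back to a ratio for
display — the averaging scale is this package's choice, documented here.
Ranked panels take the top 10 increasing and top 5 decreasing genes at
max sFPKM ≥ 5, the decreasing panel in ascending order (most decreasing
first).  Category panels come from an editable annotation TSV seeded with
receptor, heat-shock, ion-channel and complement genes; the receptor
panel uses a relaxed floor of 1 sFPKM because receptor genes are lowly
expressed.

## Exon usage

Usage = (exon + 0.5)/(gene total + 1) per sample; logit-usage is compared
between two groups with the moderated-t machinery (unit weights), BH
across all tested exons; single-exon genes are skipped with a notice.
This "JunctionSeq-style (simplified)" test keeps the defining property —
it responds to relative usage, not overall induction (verified by an
invariance test) — but makes no claim of numerical agreement with
junction-level GLM tools.  A usage shift of 0.2 at the study's group
sizes and ~500 counts/sample is detected with ≥ 80 % power.

## Puncta statistics

Intensities (0–255) are binned per 10 levels into 26 bins; the final bin
[250, 255] is truncated because the scale does not divide evenly (the
choice is recorded in output headers).  Binned counts are log₁₀(x+1)
transformed and analyzed with a mixed repeated-measures two-way ANOVA
(between = treatment, within = bin, subject = animal; Greenhouse-Geisser
correction on within-subject tests by default), with per-bin treatment
contrasts Holm-Šidák adjusted.  Degenerate inputs with zero residual
variance return p = 1 throughout rather than failing.  Co-expression 2×2
tables use Pearson's chi-square without continuity correction (df = 1).

## Numerical and design notes

* Matrices reject missing values; there is no imputation step.
* TSV round-trips are bit-exact (shortest-repr floats on write,
  round-trip float parsing on read).
* QC excludes a sample when the Pearson correlation of its log₂(x+1)
  profile with its experiment's median profile falls below 0.9 (the
  criterion is covariation; the statistic and cutoff are this package's
  choices).
* The CLI fans a single global seed into per-stage child seeds by stable
  hashing of stage names, so toggling stages never changes another
  stage's draws; manifests record stage, seed, parameters and version.
* Problem sizes in tests and examples (typically 300–2000 genes, one or
  a few experiments, 3–20 seeds) are desk-scale choices that keep the
  suite fast while leaving Monte-Carlo error well inside the asserted
  margins.

## Known limitations

Plain FPKM stands in for sFPKM (no insert-size or contamination
adjustment).  The simulator's magnitudes beyond T½ and the 50 % rebound
fraction are free parameters, not estimates of the underlying biology.
Genome-wide DEG counts and the published consensus list require the real
sequencing data and are out of scope.  One published figure quotes an
oxidative-stress gene's "10 h/control" ratio of 7.29 where the
corresponding table prints 5.86; 7.29 equals the 10 h-vs-recovery
pseudocount ratio, so the prose value appears to be the maximum pairwise
ratio under a mislabeled comparison — the package computes both and takes
no side.  Likewise the amygdala increasing-gene count is printed as 992
in one place and 991 in another; the direction summary yields 87 % up
either way.
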