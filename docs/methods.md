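# Methods

## Data model and scope

The pipeline starts from protein-level reporter-ion intensity tables (one per
TMT batch) and a study design mapping channels to batch, sample, growth
condition, replicate and bridge status. Peptide-spectrum matching and protein
inference are out of scope; intensities are taken as given. A reporter
intensity of zero and an empty cell are both treated as "not quantified":
zero is not a usable measurement on a multiplicative scale.

**Complete-case filter.** Only proteins quantified in every channel of every
batch are analyzed. Filtering is done *before* normalization: column sums and
TMM are undefined on matrices with missing values, and for proteins complete
in all channels the SL/IRS factors are unchanged by the order, so the
retained set is identical either way. The run report always states the
detected and quantified counts so the choice is auditable.

## Normalization cascade

All three steps are multiplicative on the linear intensity scale; the working
scale for statistics is log₂ (complete-case values are strictly positive, so
no pseudocount is introduced).

**Sample Loading (SL).** Within a batch, channel j is multiplied by
(mean of column sums)/(sum of column j). Assumes equal total protein was
labelled per channel; corrects pipetting/labelling differences. SL operates
on the protein-level table (the available data); the factor definition is
identical in form to the spectrum-level version.

**Internal Reference Scaling (IRS).** Per protein p and batch b, the
arithmetic mean of p's bridge-channel intensities is computed
(bridge_mean(p,b)); the within-batch combination is arithmetic because the
bridges are replicate measurements of the same pooled material. The
cross-batch reference is the geometric mean over batches of bridge_mean(p,·)
— the natural average of multiplicative scale factors, and it makes the
result symmetric in batch order. All of p's intensities in batch b are
multiplied by reference(p)/bridge_mean(p,b). Both combination choices are
isolated in one function and easy to switch. Post-condition (tested to
machine precision): every protein's bridge means agree across batches.
Proteins with a zero/undefined bridge mean are dropped with a warning and
listed in the factor record.

**TMM (trimmed mean of M-values).** Factors are computed on column-sum-scaled
proportions, so they are invariant to each channel's overall scale. The
reference channel is the one whose 75th-percentile proportion is closest to
the mean of 75th percentiles. For channel k vs reference r, per protein:
M = log₂(p_k/p_r), A = ½·log₂(p_k·p_r). Rows in the top/bottom 30 % of M or
5 % of A are trimmed (rank-based bounds ⌊n·trim⌋+1 … n−⌊n·trim⌋, average
ranks for ties, i.e. midpoint tie-breaking). The factor is
2^(weighted mean of surviving M) with inverse-variance weights from the
binomial approximation evaluated on proportions at unit depth,
v = (1−p_k)/p_k + (1−p_r)/p_r. Intensities carry no natural count scale, and
the unit-depth form keeps the factors exactly invariant under global
rescaling of any column — a property the depth-dependent count weights do
not have. Factors are rescaled to geometric mean 1. If fewer than 2 rows
survive trimming, the untrimmed weighted mean is used with a warning. The
normalized matrix divides each column by (factor × column-sum scale), which
keeps the output on the original intensity magnitude.

## Differential abundance

A one-way fixed-effects layout over the conditions is fitted per protein on
the log₂ matrix, bridges excluded: condition means are replicate averages,
the residual variance s²_g is pooled within conditions, and
d_g = n_samples − n_conditions (12 for the 18-sample/6-condition layout).
No batch covariate is included — IRS has already removed the protein-specific
batch term, and the fit would lose degrees of freedom to a nuisance the
bridges estimate better.

**Variance prior.** Moment matching on e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2):
the prior df solves ψ′(d₀/2) = var(e) − ψ′(d_g/2) by Newton inversion of the
strictly decreasing trigamma (unique root; tolerance 1e-8, bounded
iterations), and s₀² = exp(ē + ψ(d₀/2) − ln(d₀/2)). When var(e) does not
exceed the sampling term, d₀ = +∞ and s₀² = exp(ē) — note this limit carries
the finite-d_g log-scale correction exp(ln(d_g/2) − ψ(d_g/2)) (≈ 1.089 at
d_g = 12) relative to the raw common variance; this is the standard
behaviour of the moment estimator, not a bug. d₀ = 0 is accepted as the
explicit no-moderation limit.

**Moderated t.** s̃² = (d₀s₀² + d_g·s²_g)/(d₀ + d_g);
t̃ = (x̄ₐ − x̄_b)/√(s̃²(1/nₐ + 1/n_b)); two-sided p on d₀ + d_g df (normal
limit at d₀ = ∞). No variance trend or robust estimation in this version.
Each unordered condition pair is computed once in declared order, so
logFC(a,b) = −logFC(b,a) by construction; BH adjustment (statsmodels
`fdr_bh`) is applied within each contrast separately, matching a per-contrast
FDR reading of significance.

## Set logic

Selection uses strict inequalities (|log₂FC| > 1, FDR < 0.05 by default);
boundary values are excluded. The any-vs-all partition returns the union
(passing vs ≥ 1 other condition), per-comparison sets, and the intersection
(passing vs all others). Quadrant selection classifies proteins jointly
significant in two parallel contrasts as both-up/both-down/mixed. Strict
group selection requires the up-rule in every A×B cross contrast. Fold
changes print as linear ratios: nearest integer at ≥ 2, one decimal below
(log₂FC 3.3 → "10"); negative values render the inverse ratio with a down
flag. Decimal points only, never decimal commas.

## Clustering and PCA

Z-scores are computed per protein across the 18 biological samples (bridges
excluded) with the n−1 denominator; constant rows become all-zero and are
reported. Clustering operates on the regulated subset (proteins passing the
two-sided rule in ≥ 1 contrast) — Euclidean distance, complete linkage by
default (the common default of the heatmap tooling family; average/ward are
switchable), rows pre-sorted lexicographically by protein id so the
partition is deterministic and order-independent, tree cut with maxclust into
k groups, cluster indices relabelled by decreasing size. k is a user
parameter with default 9, mirroring the reference study's heatmap grouping.
PCA treats samples as observations and proteins as centered variables;
explained-variance fractions sum to 1.

## Synthetic-data generator

Signal model per (protein, channel), log₂ scale:

  baseline + condition effect + batch effect·1[batch 2] + channel loading + noise

with baseline ~ N(20, 2²), noise sd 0.25, channel loading sd 0.3
(channel-specific, shared by all proteins), and a protein-specific batch-2
offset with sd 0.5 — exactly the structure IRS can remove. Bridge channels
are built on the linear scale as the arithmetic mean of the 18 biological
true signals (a pool mixes mass, not logs) and then receive their own batch
effect, loading and noise. Dropout masks each (protein, channel) cell
independently at rate 0.05. Six archetypes give every selector a non-empty
ground truth: constitutive (all effects 0), fermentation-specific up/down
(±1.5 in Py-only), electron-donor-specific (H₂-up: +1.5 in both H₂
conditions; lactate-up: +1.5 in both lactate conditions), and
electron-acceptor-specific (ClOHPA-up: +1.5 in both ClOHPA conditions); the
five regulated archetypes default to 2 % each (10 % regulated overall).
Samples are split over two batches in a balanced layout — every condition
spans both batches (first three conditions: replicates 1–2 in batch 1;
last three mirrored) — as a well-designed multi-plex experiment would be
randomized. The magnitudes are package choices (the reference design states
none); they describe a realistic, well-behaved TMT experiment.

What the generator does **not** emulate: peptide-level aggregation, ratio
compression from co-isolation interference, intensity-dependent (MNAR)
missingness, correlated noise between channels, or partially overlapping
regulation patterns. Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated model, not performance on
real MS data, where ratio compression in particular attenuates fold-changes.

## Accuracy floors and the value of IRS

With 3 replicates and noise sd 0.25, the log₂FC estimate carries an
irreducible noise floor of 0.25·√(2/3) ≈ 0.20 sd (median |error| ≈ 0.14).
IRS removes the protein-specific batch term exactly, but its correction is
itself estimated from 2 noisy bridge channels per batch, so the residual
bridge-noise it injects into cross-batch contrasts has the same order as the
batch contamination it removes has at these settings. Consequently the
median-error improvement from IRS at the default nuisance magnitudes is real
but modest (≈ 10 %); the improvement grows with batch-effect sd and with the
number of bridge channels, and the monotonicity of the no-IRS error in the
batch-effect sd is part of the test suite. Disabling IRS is surfaced as a
bridge-disagreement QC warning in the run report.

## Problem sizes and numerical tolerances

Default simulations use 2000 proteins (a paper-scale 4851 is one config
field away); recovery statistics in the verification suite pool 5 seeded
replicates. SL column sums match their grand mean to < 1e-12 relative;
post-IRS bridge agreement is checked at machine precision (< 1e-12
relative); TMM factors match an independently coded brute-force oracle to
1e-9 and have geometric mean 1 ± 1e-12; the moderated-t path matches a
formula-by-formula oracle at 1e-12. Prior recovery on 5000 draws with true
d₀ = 4, s₀² = 0.04, d_g = 12 lands within 15 %/10 % of truth. All randomness
flows from a single integer seed per run; identical seeds give bit-identical
outputs.
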