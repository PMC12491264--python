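# Methods

## Scope and model

The package implements a discovery pipeline for multi-omic signatures of
regulated cell death (RCD) in cancer. Its statistical core is deliberately
simple and univariate: rank correlation for the genome-wide screens,
rank-sum tests for tumor-vs-normal polarity, univariate Cox proportional
hazards and Kaplan–Meier/log-rank for survival contexture, and Spearman
correlation against deconvoluted cell-infiltrate scores for immune
contexture. No clinical covariates (age, sex, stage) enter the survival
models at this discovery stage — the goal is large-scale, systematic
screening, not adjusted effect estimation, and every emitted code should be
read accordingly.

### Screening and multiplicity

Each screen is one (cancer type × omic layer × phenotype) family: every
feature of the layer against one of the three tumor-intrinsic indices
(TMB, MSI, TSM). Spearman's rho uses average ranks for ties and the
two-sided *t* approximation for *p*; |rho| = 1 is assigned *p* = 0.
Families are adjusted with Holm–Bonferroni (step-down; statsmodels
`multipletests` behind the package surface), and the genome-wide gate is
*p*<sub>adj</sub> < 5 × 10⁻⁸. Defining the family per screen keeps that
threshold meaningful at genome scale while letting separate cancers and
layers stand alone. Zero-variance features and features with fewer than 3
non-missing samples are excluded and reported with a reason, never emitted
as rho = 0.

All downstream, per-feature annotations use unadjusted *p* < 0.05: they are
descriptive contexture for features that already passed the genome-wide
gate, not additional discovery claims.

### Tumor-vs-normal polarity (TNC)

Two-sided unpaired rank-sum tests per gene, adjusted across genes within a
cancer type by Benjamini–Hochberg (the conventional transcriptome-wide
choice; configurable). Codes: 0 no data (no normals), 1 unchanged
(*p*<sub>adj</sub> ≥ 0.05), 2/3 under-/overexpressed by the tumor–normal
median comparison. A significant test with exactly tied medians is coded
unchanged — a documented, deterministic resolution of a degenerate case.

### Survival contexture (HRC and SMC)

HRC fits one univariate Cox model per endpoint (DSS, DFI, PFI, OS — this
order indexes every 4-letter array). Letters: A when *p* ≥ 0.05 or the fit
was skipped, B when *p* < 0.05 and HR > 1, C when *p* < 0.05 and HR < 1.
Endpoints with fewer than 2 events, constant covariates, or non-converged
fits (including |log HR| > 50, which flags separation) are coded A with an
explicit flag rather than dropped.

SMC contrasts patient groups by log-rank test. Groups per layer:
continuous layers split at the median with exact-median samples assigned
to Low (deterministic); mutation splits carriers (MT = 1) vs wild type;
CNV first contrasts Deleted ({−2, −1}) vs Duplicated ({1, 2}) with neutral
samples excluded, and only if that contrast is non-significant (or a group
is empty) falls back to pooled non-neutral vs neutral, coded D when the
pooled group fares worse. A significant pooled contrast in which the
*neutral* group fares worse has no letter in the code vocabulary and is
coded A. Direction ("which group fares worse") is decided by restricted
mean survival time up to the smaller of the two groups' largest observed
times — robust when median survival is undefined under heavy censoring.

The dichotomization quantile for continuous features is a design choice of
this package (median split), as is the tie rule; both are isolated in one
place and configurable in spirit: the grouping logic lives in a single
function per layer kind.

### Bi-layer annotation

Expression-based annotations (TNC, HRC, TMC, TIC, and SMC for continuous
layers) of protein, mutation, CNV and methylation features are computed
from the companion mRNA of the same gene locus: sparse binary mutations,
ordinal copy-number states and probe-limited methylation do not support
expression-style inference directly. Mutation and CNV keep their native
categories for Kaplan–Meier grouping, where the letter vocabulary defines
them. The feature → companion mapping is data (the parent-gene column of
each layer), not inference.

### Microenvironment (TMC) and immune (TIC) contexture

A feature's profile is its Spearman rho and *p* against each of 29
cell-infiltrate scores. Correlations are first converted to *presence*
(+1 more present, −1 less present): underexpressed features flip the raw
sign, because a gene that is low in tumors correlates positively with a
cell type only where the tumor phenotype is weakest. TMC sums |rho| over
significantly correlated, presence-indicating cells within each tumor role
and takes the largest aggregate (1 anti-tumoral, 3 pro-tumoral, 2 dual;
4 when nothing is significant; an exact tie at the top is dual). The sum
of |rho| over presence-indicating significant cells is the simplest
aggregate consistent with a "combined magnitude, considering signs" rule;
it is isolated in one function so an alternative weighting can be swapped
in. TIC compares a hot score (presence-adjusted rho over CD8⁺ T, NK
activated, M1) with a cold score (M2, Treg); near-ties within 10⁻⁹ are
re-decided with the cytotoxic (CD8/NK) markers weighted ×2 — those cells
carry the hot/cold distinction — and a residual tie is "variable".

The 29-cell role assignment ships as an editable TSV
(`data/cell_categories.tsv`): cytotoxic CD8/NK/M1 anti-tumoral, M2/Treg/CAF
pro-tumoral, the remainder dual. These defaults follow the standard
immuno-oncology reading of these populations; users with a different
consensus edit the file, not the code.

### Signature grouping and identifiers

Signatures are mono-omic: features from one layer of one cancer sharing
the exact tuple (phenotype, correlation sign, TNC, HRC array, SMC array,
TMC, TIC) *and* the identical gene-level RCD form set (intersection equals
union — features whose parent genes differ in form set never merge). The
grouping is a strict partition; GSI numbers are assigned by sorting
(layer, phenotype, first member id) within each cancer and numbering from
1, so shuffled input reproduces identical output.

Composite scores are member-wise sums of the (companion) expression
values, unstandardized by default because the construction is literally
additive; a z-score option exists behind a flag. Composite re-evaluation
runs the same Cox/log-rank machinery on the sum (always continuous, hence
High/Low grouping); disagreement with the member-shared arrays sets a
recorded flag and logs a warning, but member-level codes stay
authoritative in the identifier — the identifier describes what the
members share.

The 4-letter array ↔ integer code mapping is data-driven. Two tables
ship: `paper_anchors` (default) is the lexicographic enumeration over
{A, B, C, D} (codes 0–255) with the five published code assignments
swapped into place (`BBBB`→44, `BCBC`→56, `CCCC`→95, `DBBD`→114; `AAAA`→0
and `AAAB`→1 hold already), each swap preserving bijectivity; `fallback`
is the plain enumeration. No positional scheme reproduces the published
assignment of 44 to `BBBB`, and the stated total of 128 array combinations
matches neither 3⁴ = 81 nor 4⁴ = 256, so the authoritative table cannot be
reconstructed from first principles; correctness of encode/decode is
defined relative to the loaded table, which is validated as a bijection at
load time, and the active table is logged and echoed in interpreter
output.

### Ranking and external validation

The rank is an additive integer score: TIC (hot 3, variable 2, cold 1, no
data 0), TMC (anti 3, dual 2, pro 1, no data 0), TNC (informative
polarity 1, else 0), one point per non-A letter in each of HRC and SMC,
plus one point per member beyond the first capped at five. The map is a
package default expressing the ordering intuitions of the framework — hot,
anti-tumoral, all-endpoint signatures rank highest — and is fully
overridable via YAML/JSON; published rank values from other
implementations are not reproduced by this default map and are not
comparison targets. Representative selection takes, per RCD form or per
omic layer, the maximum under (rank, member count, TIC, TMC, SMC, HRC)
with a final deterministic fallback on identifier string order; per-layer
mode back-fills any layer missing from the selection with its best-ranked
signature.

Meta-Z validation: the signature-level score is the median meta-Z over
member genes found in the table (missing genes excluded and counted; all
missing → missing verdict). The expected prognosis direction comes from
the HRC array — a risky or protective OS letter dominates, otherwise the
majority across endpoints, otherwise validation is skipped with reason.
Validated means |Z| > 3.09 (two-sided *p* < 0.001) with matching sign
(positive Z = poor prognosis).

## The synthetic-data generator

The generator produces the *logical shape* of a pan-cancer multi-omic
study with fully known ground truth. Per cohort: seven layers with correct
codomains (mutations in {0, 1} at 5% default prevalence; CNV in {−2..2}
with marginals 0.02/0.18/0.60/0.18/0.02, a plausible gistic-thresholded
shape; methylation in [0, 1]; log-normal expression), three continuous
phenotype indices, four exponential survival endpoints with administrative
censoring at the requested quantile of the event-time distribution
(reproducible censoring fractions), 29 infiltration scores built from a
shared latent immune axis plus per-feature planted loadings (strength 0.5),
and matched non-tumor mRNA/transcript expression.

Correlations are planted through a Gaussian copula: feature and phenotype
share a latent bivariate normal with Pearson r = 2 sin(π ρ<sub>s</sub>/6) —
the exact Pearson↔Spearman relation under bivariate normality — and each
margin is transformed monotonically, which preserves rank correlation in
population. Discretized layers (mutation, CNV) attenuate the realized
Spearman below the nominal target; planted effects on those layers should
be specified with that in mind. Effects planted on non-mRNA layers couple
the parent gene's mRNA latent to the same signal, so the companion-based
annotations see the biology a real coupled locus would show. TMB, MSI and
TSM are modelled only as continuous scores on monotone scales; the
pipeline consumes them through rank correlation alone, so their marginal
shapes are presentational.

The RCD inventory generator treats each of the 25 forms as an independent
per-gene Bernoulli. The apoptosis marginal is pinned at its requested
frequency (default 81.4%) and the other marginals are rescaled by one
bisection-calibrated factor so the *expected* multi-form fraction equals
the request (default 40%); genes drawing no form receive a single
non-apoptosis form, keeping the apoptosis fraction on target. This single
mechanism also yields ≈ 43% apoptosis-only genes without a separate knob.
The non-apoptosis default frequencies are ordered plausibly (autophagy and
necrosis common; alkaliptosis, lysosome-dependent cell death and methuosis
rarest) and sum near the calibrated value, so the rescaling factor stays
close to 1.

What the generator does *not* emulate: batch effects, molecular subtype
structure, inter-gene correlation beyond the planted couplings,
non-proportional hazards, informative censoring, or realistic marginal
distributions of any index. Passing tests therefore demonstrate that the
pipeline recovers effects of the planted kind under clean conditions and
controls its error rates under the null — not that it would rank real
cohort signatures identically to any particular published analysis.

## Numerical choices

* Spearman screening is vectorized (rank, center, matrix product); tests
  pin it to a naive rank-then-Pearson oracle at 10⁻¹² and to
  `scipy.stats.spearmanr`.
* Holm and BH adjustments delegate to statsmodels; a brute-force step-down
  oracle over all permutations of ≤ 6 p-values guards the Holm path.
* Cox fits use lifelines with convergence failures, < 2 events, constant
  covariates and |log HR| > 50 all coded A with flags.
* Exact ties: TMC/TIC aggregates compare within 10⁻⁹; median-split ties go
  to Low; signature ordering falls back to identifier strings.
* Rounding of reported percentages/ratios is decimal half-up at the
  printed precision, so reports regenerate byte-identically.
* Every stochastic path takes an explicit integer seed; the analysis
  engine itself is deterministic.

## Problem sizes used in tests and the acceptance script

The calibrated end-to-end run uses four cohorts × 500 genes
(2,000 genes, 250 tumor / 40 normal samples each, five planted effects
per cohort across five layers) — large enough for the genome-wide gate to
separate planted from null features with margin, small enough to iterate
on. Calibration suites use 1,000 null survival simulations at n = 200,
20 recovery seeds at n = 500, 50 contexture profiles at n = 300, and a
10,000-entry null meta-Z table. These sizes are the package's standing
choices and are printed in the acceptance output as each quantity's `n`.

## Known limitations

* Hazard-class letters come from marginal tests; correlated endpoints
  (PFI/DFI/DSS overlap) are not modelled jointly.
* The aggregation behind TMC/TIC is one defensible reading of a
  "combined magnitude" rule; alternatives (signed sums, weighted means)
  would reclassify borderline profiles. The function boundary makes the
  swap trivial.
* The array↔code table beyond its anchored entries is a package
  convention, not an external standard.
* Companion-based annotation assumes the parent gene's mRNA is the right
  proxy for protein, mutation, CNV and methylation features; loci with
  discordant regulation violate that assumption.
* Discrete-layer screens lose power through rank attenuation; a planted
  |ρ| = 0.6 mutation effect at 5% prevalence is near the detection
  boundary at n = 400.
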