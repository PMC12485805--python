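# Methods

## The generative model

picsim models a peak-by-cell paired-insertion-count matrix with four
independent, estimable components. Library sizes are log-normal:
`ln L_j ~ N(μ, σ²)`, fitted by the log-moment MLE of column totals. Peak
means `λ_i` follow a member of the generalized gamma family — Weibull
(shape η, scale κ) by default, with gamma, Pareto and a two-component
lognormal-gamma mixture as alternatives — fitted by maximum likelihood to
the nonzero per-peak means of depth-normalized counts (each cell scaled to
the median total; the lower median over positive-total cells, for
determinism). Counts are conditionally Poisson with mean `λ̄_i·L_j`, where
`λ̄_i = λ_i/Σλ`, so a cell's expected total equals its library size.
Finally a Bernoulli sparsity layer zeroes additional entries per cell.

Only the *shape* of the peak-mean distribution is identifiable: because the
simulator renormalizes the means, the fitted scale equals the true scale
times `median_library/Σλ`. Round-trip tests therefore compare the fitted
scale against the scale of the normalized means, not the latent one.

### Sparsity semantics

`π_j` is defined as the **target final zero fraction** of cell *j*, because
that is what estimation measures (the realized zero proportion). The
Poisson layer already produces structural zeros at rate `z0_j`; masking is
calibrated to the remainder: each nonzero entry is zeroed with probability
`q_j = max(0, (π_j − z0_j)/(1 − z0_j))`. An alternative reading — masking
*all* entries at rate π — would make realized sparsity exceed π whenever
structural zeros exist and break the estimate→simulate round trip; the
calibrated form is the testable contract.

When a π vector must be assigned to freshly simulated cells, targets are
matched to cells by library-size rank: the deepest cell receives the
smallest target (resampling with replacement first extends the vector if
more cells than estimates are requested). Per-cell sparsity anticorrelates
strongly with depth in real data; a random pairing would mask deep cells at
high rates and visibly shrink the simulated library-size distribution.

**Known limitation.** Masking removes counts, so when π sits materially
above the structural zero rate the realized library sizes fall below the
sampled `L_j` by roughly a factor `(1 − q_j)`. In well-fit real data the
Poisson layer explains most zeros and the Bernoulli layer is a small
top-up, so the loop closes; the package's calibration tests use that
self-consistent regime (the `pi="structural"` fixture mode sets each cell's
target to its realized Poisson zero fraction, keeping the truth π exactly
calibrated while leaving masking inactive). A fixture with heavy masking is
still useful for stress-testing sparsity handling, but its estimated
parameters describe the *realized* (post-masking) depth, and re-simulating
from them under-shoots the reference depth — inherent to this generative
family, since depth-with-masking and lower depth are observationally
equivalent at estimation time.

## Dispersion (BCV)

The common biological coefficient of variation φ anchors a per-peak trend
`BCV_i = (φ + 1/√mean_i)·√(df₀/χ²_{df₀})` — larger means get lower BCV, and
the χ² draw gives the scaled inverse chi-squared spread with prior degrees
of freedom df₀. Cell-specific means are gamma draws with `E = λ_{i,j}` and
`CV = BCV_i` (shape `1/BCV²`, scale `λ·BCV²`).

The raw common dispersion is a two-stage method-of-moments estimate:
per-peak `(var − mean)/mean²` on depth-normalized counts, then a
precision-weighted (weights ∝ peak mean) 10%-trimmed mean across peaks.
A linear correction `φ = −0.3 + 0.15·φ_raw` is applied, clamped below at
`ε = 1e−4` because the line crosses zero at `φ_raw = 2` and BCV must stay
positive. df₀ is the method-of-moments df of a scaled inverse chi-squared
fitted to `φ_raw/d_i` ratios (variance `2/df₀`), clamped to [1, 100] with a
default of 8 when the estimate is unstable; no closed form is canonical for
this quantity, so the moment estimator was chosen for transparency.

## Groups and batches

Each cell draws an i.i.d. categorical group label. Per group, each peak is
differentially accessible with probability 0.13 by default (the fraction
reported for typical scATAC-seq cell-type comparisons); DA factors are
`exp(N(loc, scale))` with defaults loc = 0.1, scale = 0.4, and a 0.5
fraction inverted (reciprocal — symmetric in log space) for down-regulation.
Batch factors are per-cell log-normal draws with batch-specific (μ_b, σ_b).

Order of effects: DA multiplies the baseline peak mean; each cell's mean
vector is then normalized; library size and the batch factor scale the
normalized vector. The batch factor must act after normalization — it is a
per-cell scalar, and any per-cell scalar applied before normalization
cancels identically. Placed there it shifts the cell's effective sequencing
depth, which is exactly how batch effects manifest in real experiments and
what makes batches separable in PC space.

With one group, no DA, one unit batch and the BCV layer disabled, the
multi-group path reduces bit-exactly to the single-type path under the same
seed: every sampling step draws from its own named RNG substream (derived
from the seed via CRC-keyed `SeedSequence` spawn keys), so e.g. changing
the number of cells never perturbs the peak-mean draw.

## Population cohorts and caQTLs

Per-individual baselines are `λ_{i,j} ~ N(λ_i, σ_i)` clamped at zero
(clamps counted and logged), with `λ_i` drawn from the across-individual
average of per-individual peak-mean fits and `σ_i = CV·λ_i·s`, the CV drawn
from the gamma law of the mean-bin containing `λ_i`. Estimation bins peaks
by across-individual mean into consecutive bins of 50 (a trailing bin with
fewer than 3 peaks merges into its predecessor, since the gamma MLE needs
at least 3 points; an all-identical bin gets a sentinel rate `β_v = 1e6`,
i.e. effectively zero CV, with a warning). Supplying empirical means and
variances bypasses the sampling and uses them directly.

caQTLs are assigned to `round(ca_peaks · n_peaks)` uniformly chosen peaks;
for each, a SNP is chosen uniformly among those within ±`ca_window` bp
(default 100 kb) of the peak midpoint (`floor((start+end)/2)`, 1-based) and
with folded MAF in `ca_maf_range` (default 0.05–0.5). Peaks with no
eligible SNP are skipped with a warning and replaced from the remaining
pool. Effects are `ω ~ Gamma(α_c, rate β_c)`, negative with probability
0.5, and act multiplicatively and dosage-linearly:
`λ_{i,j} × (1 + sign·ω·G_{i,j}/2)` — heterozygotes get half the effect,
matching the additive-dosage convention of population-scale single-cell
simulators. Condition-level DA applies log-normal factors (reciprocal for a
configured down fraction) to non-reference cohorts, the reference being the
first condition label in sorted order. No linkage disequilibrium is
synthesized beyond what the input genotypes carry.

Default effect-size law `Gamma(α_c=2, β_c=4)` (mean 0.5, sd ≈ 0.35) gives a
spectrum of mostly modest multiplicative effects with an appreciable tail —
the shape empirical caQTL scans report; inter-individual CV defaults
`Gamma(α_v=2, β_v=10)` (mean CV 0.2) and `s = 1` put genotype effects and
baseline inter-individual noise on comparable scales, so detection is
neither trivial nor hopeless at realistic cohort sizes.

Pseudobulk aggregation depth-normalizes cells (median library size), takes
per-peak means within individuals, and optionally rank-transforms each peak
to a standard normal across individuals (exactly standardized per row, ties
permitting) — the conventional phenotype transform for QTL mapping, which
the package emits mapper-ready together with the truth tables.

## Diagnostics

For library size (natural-log scale by default), peak mean and cell
sparsity, real and simulated vectors are sorted and compared elementwise:
MAD (median of absolute differences — the median form is used, being
robust to outliers), MAE, RMSE, and 1 − Pearson correlation of the sorted
vectors. Unequal lengths are reconciled by linear quantile interpolation of
the longer vector, which preserves the distributional semantics. A
zero-variance input makes the correlation undefined; it is reported as NaN
with a warning. Summary statistics cover per-cell library size and
sparsity and per-peak mean, variance, zero and nonzero proportions, plus
the paired mean-zeros / mean-variance / mean-nonzero relations.

## Synthetic inputs and what they do (not) show

All fixtures are generated from the model itself: counts by exact forward
simulation with truth attached; genotypes as Hardy-Weinberg draws
(`(1−p)², 2p(1−p), p²`) at uniformly placed biallelic SNPs with
`MAF ~ U(0.05, 0.5)`; peaks as sorted non-overlapping intervals written as
matched BED and GFF3. Defaults mirror a mid-depth droplet library:
log-library μ = 8.5 (median ≈ 5,000 fragments/cell), σ = 0.35; Weibull
shape 0.8 (heavy-tailed, sub-exponential peak means), scale 0.3; target
sparsity 0.8; a 50-Mb chromosome at chr22-like SNP density.

Because fixtures come from the model, passing tests demonstrate internal
consistency — correct implementation of estimation and simulation and their
round trip — not that the model captures every property of real chromatin
data. Features deliberately not emulated: fragment-level structure, LD,
peak co-accessibility, doublets, and the per-donor technical idiosyncrasies
that make some individuals form distinct clusters in real cohorts.

## Problem sizes and numerical choices

Test and acceptance runs use desk scales chosen to keep Monte-Carlo error
well inside the asserted tolerances: 5,000 peaks × 1,000 cells for
parameter recovery; 83 individuals × 100 cells × 2,000 peaks (70% caQTL
coverage, ≥500 null peaks) for sign-recovery and type-I checks; 10,000-cell
draws for proportion checks. Distribution fits use scipy MLE with location
pinned at zero and method-of-moments initialization; the mixture fit is a
bounded EM (≤300 iterations, log-likelihood tolerance 1e−8). Ties in
medians break low; all dropped cells/peaks/SNPs are counted and logged;
negative baselines and genotype-adjusted means clamp to zero with logged
counts.
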