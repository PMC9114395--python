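# Methods

This note documents the models, conventions, and numerical choices
behind `cryptphylo`, and what the synthetic cohorts do and do not
emulate.

## The data model

A patient contributes a variant × crypt grid of (alt reads, total
reads). Crypts are clonal: a somatic mutation carried by a crypt's
founding lineage sits near VAF 0.5 (heterozygous, copy-neutral), and a
crypt is accepted as clonal when its median somatic VAF exceeds 0.3.
Germline SNPs are heterozygous in every crypt; library artifacts recur
across crypts at low VAF with unusually *consistent* allele fractions.
Copy-number events are out of scope: samples can be flagged `cnv` and
are then excluded from germline-test pooling, but expected VAFs are
never CN-adjusted.

## Synthetic cohorts (`simdata`)

**Tree.** A random coalescent-join topology over crypts. Time runs
from 0 (zygote) to 1 (sampling); every internal node is placed inside
an early developmental window (default first 2% of the timeline), so
clade-shared mutations are few while each crypt's private terminal
branch spans nearly the whole lifetime — the structure real crypt
phylogenies show, since crypt lineages separate during development.
Root-to-leaf time fractions sum to 1 by construction.

**Mutations.** Per branch, the somatic count is Poisson with mean
(branch time-fraction) × (age) × (Σ signature activities in
mutations · yr⁻¹); each mutation's channel is drawn from its
signature's probability vector and converted into a concrete variant
(trinucleotide context for SBS; motif plus flanking sequence for
indels) such that the spectra classifiers re-derive the channel
exactly, including random purine-strand representation for SBS and
1-bp indels. Early internal branches carry additional embryonic
mutations (Poisson, default mean 10 per branch) — these provide the
clade-defining characters. Contexts are short synthetic strings; no
reference genome is used or needed.

**Reads.** Depths are Poisson around 30; carrier cells draw alt counts
Binomial(depth, 0.5), non-carriers Binomial(depth, 0.001), germline
sites Binomial(depth, 0.5) everywhere, and artifact sites
beta-binomial with mean 0.1 and overdispersion ρ = 0.02 in every
crypt.

**Desk scale.** Default activities sum to 10 SBS and 0.5 ID per year
at age 50 — thousands of somatic variants per patient rather than the
hundreds of thousands a real genome-wide call set contains. All
filter thresholds are rates and fractions, so recovery behaviour is
scale-free; analyses that state a rate (e.g. 55 SBS · yr⁻¹ for burden
recovery) set it explicitly. The tumour clade grafts onto a normal
terminal branch at depth 0.7 and places a Poisson(50,000) trunk at
depth 0.98, reproducing a recent clonal expansion from a heavily
mutated ancestor.

**What passing tests do not show.** The generator has no population
SNP structure (germline removal by panel-of-normals is out of scope),
no copy-number or structural variation, no subclonality within crypts,
no mapping or context-dependent error, and artifact VAFs follow a
convenient beta-binomial rather than any chemistry-derived law. Tests
therefore establish correctness of the statistical machinery under the
stated model, not robustness to every failure mode of real libraries.

## Filtering

The germline test pools alt/depth over CNV-free crypts and computes
the exact one-sided binomial tail P(X ≤ alt | depth, 0.5); p-values
are Benjamini–Hochberg adjusted and a site is germline when its
adjusted p ≥ α (default 10⁻⁵ — the test names the procedure, and this
conservative default retains as somatic only sites clearly below 0.5;
it is configurable and recorded in output). With 8 crypts at 30X a
variant private to one crypt has aggregate VAF ≈ 0.06 and survives
easily; variants shared by nearly all crypts are indistinguishable
from germline — in the generator such branches carry only a handful
of mutations, which bounds somatic loss below 1%.

The beta-binomial is parameterized by mean μ and overdispersion ρ via
α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ. μ is plugged in as the pooled alt
fraction (clipped to [10⁻⁶, 1−10⁻⁶]); ρ is maximised by a 200-point
log-spaced grid scan over (10⁻⁶, 1−10⁻⁶) followed by bounded Brent
refinement between the flanking grid points (xatol 10⁻⁷). The
combination tracks a 10,000-point dense-grid oracle to better than
10⁻³ even where the profile is nearly flat (degenerate all-zero sites
push both to their upper bounds). Thresholds are strict: ρ exactly at
0.1/0.2 is kept.

## Phylogeny

Genotype codes use strict inequalities (VAF > 0.3 → 1, < 0.1 → 0,
else "?"; zero depth → "?"). Parsimony is Fitch small-parsimony over
binary states with "?" as {0,1}; the zygote constraint is the root
state set intersected with {0}, one extra change if empty. This
equals adding a pendant all-zero outgroup: a variant present at the
root of the sampled tree costs one change on the stem — not one per
root child, which matters for characters shared by almost all crypts.

Exhaustive search enumerates all (2n−3)!! rooted resolved topologies
(n ≤ 9). The heuristic runs random-order stepwise addition, then
alternates nearest-neighbour-interchange and subtree-prune-regraft
hill climbing to a joint local optimum, over 20 seeded restarts by
default; on 70 stress instances with 5–7 leaves and heavy homoplasy
it attained the exhaustive optimum in every case. Co-optimal trees
are tie-broken by the lexicographically smallest canonical Newick
string (children sorted), for reproducibility. Bootstrap replicates
resample genotype columns with replacement ("?" retained) and use the
faster stepwise+NNI search; supports are the percentage of replicates
containing each internal clade.

Branch placement maximises the two-rate binomial likelihood with
clonal VAF 0.5 and error rate 0.001 (both configurable), over all
branches plus an off-tree "unassigned" category in which every crypt
is at the error rate — contradictory variants are not forced onto the
tree. Posteriors are likelihoods normalised under a uniform prior.
Branch lengths of reported trees are assigned SBS counts.

## Spectra

SBS channels are ordered substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G) then 5′ then 3′ flank, each A<C<G<T; purine-strand input is
reverse-complemented first. ID83 uses COSMIC-style labels with these
semantics: for deletions the repeat-unit field counts the deleted
copy (1…6+), for insertions the pre-existing copies (0…5+). Indels
are assumed left-aligned; repeat units for multi-bp motifs are counted
on the 3′ flank. Homopolymer runs for 1-bp events are counted over
*both* flanks: strand normalization maps a 3′ run to the 5′ side, and
two-sided counting is the unique convention invariant under it (it
coincides with 3′ counting for left-aligned pyrimidine input).
Microhomology is the longest proper prefix of the deleted motif at
the start of the 3′ flank or suffix at the end of the 5′ flank,
evaluated only when no full adjacent copy exists. The branch-spectra
cap (2,500) subsamples randomly with a seed rather than truncating,
preserving the spectrum in expectation; the ≥ 100 inclusion rule and
the cap are both configurable.

## Signature extraction

**HDP backend.** Mutations are categorical draws over channels from a
three-level hierarchical Dirichlet process: a top-level DP over
channel distributions (uniform Dirichlet base, concentration γ),
patient-level DPs (α₀), branch-level DPs (α₁). Sampling is
direct-assignment Gibbs: per-mutation cluster indicators with
collapsed Dirichlet-multinomial cluster likelihoods, auxiliary
Chinese-restaurant table counts at branch and patient level, global
and patient stick weights resampled from Dirichlets, and all three
concentrations resampled under Gamma(1,1) hyperpriors by the
Escobar–West auxiliary-variable method. The inner sweep is
JIT-compiled. Desk-scale MCMC defaults are 2,000 burn-in, 50 samples
at spacing 10; the study-scale settings (80,000 / 2,500 / 250) are
accepted through the same `mcmc` dict. Posterior samples are
summarised by greedy cosine matching of per-sample cluster spectra to
running exposure-weighted centroids (threshold 0.9), followed by the
merge rule (pairwise cosine ≥ 0.9) and the minimum-support rule
(exposure > 1% in ≥ 2 branches); final exposures are an EM refit of
each branch onto the merged components. Which posterior summary the
original tooling used is not derivable from its outputs; this scheme
is this package's documented choice and is validated by recovery and
backend-agreement tests.

**NMF backend.** Multiplicative-update NMF under generalized
Kullback–Leibler divergence (scikit-learn's `mu` solver), seeded
restarts per candidate rank; restart components are matched to the
best-objective solution by greedy cosine assignment and scored by a
cosine silhouette; the chosen rank is the largest with mean
silhouette ≥ 0.8 (rank 1 is scored by mean cross-restart cosine).

**Deconvolution.** EM for mixture weights w maximising
Σ_c x_c log(Σ_k w_k R_ck): responsibilities z_ck = w_k R_ck / Σ_j w_j R_cj,
update w_k ← Σ_c x_c z_ck / Σ_c x_c; convergence at max|Δw| < 10⁻⁸ or
10,000 iterations. The objective is non-decreasing (standard EM
guarantee, asserted numerically in tests). "Contribution" means the
EM weight; reconstitution keeps weights strictly above the threshold,
renormalises, and accepts at cosine > 0.9. Residual signatures are
max(0, component − Σ selected w_k R_k), renormalised — subtraction
uses the raw EM weights and renormalisation happens after clipping
(the pre-normalisation residue is recoverable by scaling). A residue
below 10⁻¹² total mass raises a degenerate-residual error. The same
operation implements both the "unknown-signature" construction and
slippage-signature cleanup of contaminated components; candidate
screening is an explicit allow-list (the catalogue subset passed in),
not a curation step.

## Burden and cohort comparison

Crypt burden is the path sum of assigned variants from root to leaf
(uncorrected for coverage; a sensitivity divisor hook exists,
default 1). Rates are burden/age; tissue summaries are medians over
survey-type crypts. The cohort test fits burden ~ age with a
per-patient random intercept by maximum likelihood (statsmodels
MixedLM), with and without a cohort fixed effect, and refers
2(ℓ₁−ℓ₀) to χ²₁. Burden (not rate) is the response, with age as the
covariate; a rate-response or random-slope variant can be fit by
passing a transformed table. Calibration and power are established by
simulation in the test suite (200 null cohorts; 3× planted difference
across 10+10 patients). Driver rules fire in priority order — known
list, truncating (nonsense/frameshift/splice) in a tumour-suppressor
list, missense at a listed hotspot — synonymous/other never flag, and
frameshifts are annotated with the microsatellite flag (repeat tract
≥ 5 units). Percentages are rounded half-up to one decimal.

## Problem sizes

Default analyses and tests run at: 8 crypts × ~6,700 sites per
patient, 20-seed recovery studies, 12-branch × 100–2,500-mutation
extraction problems, 200 + 50 mixed-model simulations, and ~55,000
sites for the tumour-fold study. These sizes make every stage exact
or well-powered while keeping the full suite and the acceptance
script in the minutes range on a single CPU.

## Known limitations

Beyond the generator's simplifications listed above: the exhaustive
tree search is factorially bounded (≤ 9 leaves); bootstrap supports
inherit the heuristic search's local optima; the HDP sampler caps the
live cluster count (default 40) and keeps a previously assigned
cluster if the cap is hit; leaf sets are limited to 64 crypts per
patient by the bitmask representation; and the mixed model assumes
Gaussian residuals, an approximation to the Poisson-like counts that
is accurate at the burden scales analysed here.
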