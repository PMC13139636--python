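# Methods

This note documents the models behind `enterostrat`, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Enterotyping

Profiles are collapsed to genus (reads in unassigned-at-rank taxa pool
into `unclassified_<parent>` labels so per-sample totals are conserved),
converted to relative abundance, and compared by the Jensen–Shannon
distance. We use √JSD by default: the square root is a true metric on the
simplex while raw JSD is not; a flag restores raw JSD. Zero abundances
need no pseudocount — JSD is finite with the 0·log 0 = 0 convention.

Clustering is PAM. Two paths share one contract: when the medoid search
space is small (roughly C(n, k)·n ≤ 2·10⁶, which covers k = 2 up to about
200 samples) every medoid set is enumerated and the global optimum
returned; otherwise the classical deterministic BUILD + SWAP local search
runs, with all ties broken toward the lowest sample index. The exact path
exists because BUILD + SWAP can land in sub-optimal local minima even on
tiny instances (the reference R implementation lands in the same ones),
and at enterotyping scale exactness is nearly free.

The cluster number maximizes the Calinski–Harabasz index computed
directly from distances via the sum-of-squares identity
W = Σ_c (1/2n_c) Σ_{i,j∈c} d²; this equals the classical centroid-based CH
whenever the distances are Euclidean and avoids the arbitrariness of
truncating a PCoA embedding. Silhouettes are computed per k but never
drive selection. Default k range is 2–6. Cluster 1 is the largest cluster
(major enterotype first).

PCoA is classical scaling of −½JD²J; negative eigenvalues stay visible in
the eigenvalue report but are excluded from the proportion-explained
denominator; axis signs are fixed by making each axis's
largest-magnitude coordinate positive.

## Diversity and permutation tests

Alpha metrics are the classical estimators: Shannon in nats (flag for
log₂), bias-corrected Chao1 = S + F₁(F₁−1)/(2(F₂+1)), ACE with rare
cutoff 10 (falling back to Chao1 when coverage is zero because all rare
taxa are singletons), and Faith PD including the root-spanning path
(flag to subtract the stem to the MRCA). No rarefaction is applied by
default; a seeded `rarefy` is available.

PERMANOVA is the one-way pseudo-F on squared distances with seeded label
permutations and p = (1 + #{F* ≥ F})/(1 + n_perm). PERMDISP follows the
standard betadisper construction: PCoA embedding keeping negative
eigenvalues as imaginary axes, distance to the group spatial centroid
(coordinate-wise median behind a flag) with the imaginary component
subtracted and clamped at zero, one-way ANOVA F, permutation p over the
fixed distances. Default 999 permutations.

## Biomarkers

The LEfSe-style screen keeps features passing Kruskal–Wallis at α = 0.05
(on relative abundance × 10⁶), then averages over 30 seeded bootstrap
rounds (2/3 subsample per group, drawn from one label-independent
permutation so renaming groups flips only signs) a per-feature effect
|w_f · (w·Δm) + Δm_f| / 2, where w is the unit Fisher-LDA direction with a
trace-scaled ridge (λ = 10⁻⁶) and Δm the class-mean difference; the score
is sign(Δm_f)·log₁₀(1 + effect) and |score| > 2.5 is reported. The
original LEfSe subclass/Wilcoxon stage is omitted — these designs have no
subclasses — so scores are not numerically identical to the original
implementation; the contractual behaviour is the threshold pair
(2.5, p < 0.05).

SIMPER averages the per-taxon Bray–Curtis terms over all between-group
sample pairs; before normalization their sum is exactly the mean
between-group Bray–Curtis (asserted in tests as an algebraic identity).

The classifier screen fixes hyperparameters (500-tree random forest,
k = 5 neighbours, default-depth trees, 2000-iteration logistic
regression) because the contract is the harness — stratified seeded 70/30
split, rank-formulation AUC, best model by AUC with alphabetical
tie-break, permutation importance as mean AUC drop over 20 seeded
shuffles — not tuned performance.

## Co-occurrence networks

Taxa are filtered at mean relative abundance ≥ 10⁻⁴ and prevalence
≥ 0.30, Spearman correlations use midranks with two-sided t-approximation
p-values (exact permutation enumeration behind a flag for n < 10), BH
correction runs across all tested pairs, and edges keep |ρ| > 0.6 with
q < 0.05. Topology conventions for possibly disconnected graphs:
harmonic closeness (classical behind a flag), eccentricity and average
path length per connected component / over reachable pairs, mean local
clustering with degree-≤1 nodes contributing zero, and deterministic
greedy agglomerative modularity (chosen over Louvain for run-to-run
reproducibility).

## Community assembly

**Sloan NCM.** With N the mean reads per sample and p a taxon's mean
relative abundance, neutral immigration–drift predicts detection
frequency 1 − BetaCDF(d̄; Nmp, Nm(1−p)) at detection limit d̄ = 1/N (one
read — the standard choice; the model itself does not fix it). m is
estimated by bounded scalar least squares on the untransformed frequency
scale over m ∈ (0, 1]; R² = 1 − SSE/SST may be negative for gross misfit
and is reported as-is. The 95 % band is the Wilson binomial interval at
the sample count, and taxa partition into above/within/below. Unobserved
taxa are excluded from the fit (their Beta shape parameter would be 0 and
they carry no frequency information).

**βMNTD / βNTI.** βMNTD is abundance-weighted:
0.5·[Σ_i f_i^A min_{j∈B} d_ij + symmetric], with the patristic diagonal
at zero so shared taxa contribute nothing (identical communities give 0).
The null shuffles taxon↔tip assignment 999 times (seeded); βNTI is the
per-pair z-score. Implementation notes: taxa are put in a canonical
sorted order first, so results cannot depend on input column order;
patristic distances are quantized to 16 bits of the matrix range — the
quantization is monotone, so minima are preserved exactly, the z-score is
scale-invariant, and only a ~10⁻⁴ relative rounding enters the abundance
weighting, far below the null sd. βMNTD agrees with the R `picante`
implementation to printed precision on reference cases.

**Raup–Crick (Bray–Curtis).** Null communities preserve each sample's
observed richness exactly (taxa drawn without replacement ∝ occurrence
frequency via Gumbel top-k; each drawn taxon receives one read; remaining
reads allocated ∝ metacommunity relative abundance) and its read total,
so every pair's null Bray–Curtis denominator is fixed. Null batches are
generated once per sample on substreams derived from the sample ID, which
makes each pair's value independent of which other pairs are computed and
turns the all-pairs computation from O(pairs) into O(samples) null
generations. RC = 2·[#(null < obs) + ½#(null = obs)]/n_null − 1.

**Process partition.** βNTI < −2 homogeneous selection; βNTI > 2
heterogeneous selection; |βNTI| < 2 with RC > 0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, otherwise drift. The quoted conditions
use strict inequalities, so exact boundary values (βNTI = ±2, RC = ±0.95)
fall to the drift bin. Pairs are classified within each enterotype
(configurable); the metacommunity for the RC null is the analysis group.

## Niche breadth

Levins B = 1/Σ_s p_s² with p_s the taxon's profile over samples; on raw
counts (the textbook formula, used by `levins_breadth`) B is invariant to
scaling. Classification compares observed B against a null that shuffles
every taxon's counts across samples independently (taxon totals
preserved), 1000 iterations, 95 % percentile interval: above →
generalist, below → specialist, else neutral. One subtlety dictates the
scale: B on raw counts depends only on the multiset of a taxon's counts,
which the shuffle preserves — such a null would never move. The
classification therefore computes B on within-sample relative-abundance
shares recomputed after each shuffle (sample totals change when columns
are shuffled independently), where the null has genuine spread and, by
exchangeability, ~5 % of taxa are flagged under null data. This is also
the ecologically defensible scale: utilization of a sample should not
grow with that sample's sequencing depth.

## Trait association

The collinearity pre-filter repeatedly finds the worst pair by |Spearman|
(> 0.6) and drops the member with the larger mean absolute correlation to
the other retained variables (ties to the later column); α-diversity
indices and body-size variables are filtered within their own families
before entering the model. RDA Hellinger-transforms the community matrix
(rows of √relative-abundance have exactly unit norm), centres columns,
standardizes constraints, and takes pseudo-F = (constrained/q)/(residual/
(n−q−1)); the global p permutes sample rows of the constraint matrix, and
marginal per-variable tests permute the residuals of the reduced model.
Zero-residual (noiseless) fits report F = ∞ rather than a sign-flipped
ratio. Enterotype membership enters as dummy-coded constraints alongside
the continuous variables.

## Synthetic data: what it emulates, and what it does not

**Two-enterotype surveys** (`simulate_enterotype_dataset`). A hierarchical
Dirichlet-multinomial: genus proportions ~ Dirichlet(θ·q_genus) per
sample (θ = 50 by default), genus mass split over member ASVs with mild
lognormal jitter (sd 0.5), read depths lognormal around 20 000 (floor
100). The two cluster base compositions share genus masses but differ by
per-genus log-offsets (sd 1.2) and a ×2.5 shift of the "Bacillota-like"
phylum in cluster 2, so cluster 2 has the higher phylum-1/phylum-2
balance; body weight differs by cluster (means 230/275 g, sd 28) while
body length (~18 cm) and tail length (~4.5 cm) do not, and BMI = weight/
length² inherits the cluster difference. Season/habitat labels follow the
default survey shape (97 samples, 63/34; spring-heavy minor cluster).
Sampling within a genus co-varies across samples, so ASV-level
co-occurrence networks on this fixture are genus-block structured — much
denser than typical real networks, which is fine for exercising the
machinery but not a topological benchmark. Each cluster draws from a
substream keyed by the cluster's own parameters, so swapping the two
clusters' parameters swaps the generated blocks exactly. Taxon ids are
assigned to simulated trees in traversal order, making consecutively
numbered ASVs (and hence genera) phylogenetically coherent, as in real
taxonomies. Strong between-sample compositional turnover (finite θ) means
the assembly partition on this fixture is dominated by apparent
heterogeneous selection; the neutral and selection regimes below exist
precisely to generate calibrated assembly signal.

**Neutral communities** (`simulate_neutral_communities`). A Moran-type
local community of N_local individuals (default 1000): per event one
random individual dies and is replaced by an immigrant (probability m)
or the offspring of a random local individual. All samples evolve in
lockstep with vectorized events — statistically identical to serial
simulation since samples never interact. Communities start as iid draws
from the metacommunity and burn in for 30 generations by default
(relaxation time is ~1/m generations; 30 covers m ≥ 0.05 to within a few
percent of stationary variance). Reads are a multinomial subsample.
Recovery calibration (50 samples, 300 taxa, 1000 reads): the fitted m is
within a few percent of truth at m ≤ 0.1 and biased upward ~+13 % at
m = 0.5 — the diffusion approximation behind the Sloan curve drops a
(1 − m/2)⁻¹ factor in the stationary Beta shape, partially offset by
binomial detection smoothing from finite reads. All recoveries sit well
inside ±30 %.

**Selection-structured communities** (`simulate_selection_communities`).
A trait evolves along the tree by early-burst Brownian motion — rate
σ²·exp(−decay·relative depth), decay = 10 by default, decay = 0 recovering
plain Brownian motion — because microbial habitat preference is conserved
deep in the phylogeny, and that depth of conservation is exactly what
βNTI assumes; under plain BM most trait variance accrues on terminal
branches and the filtered set scatters across clades, leaving almost no
within-group signal at a 200-taxon scale. Each group's optimum is either
a number on the standardized trait scale or `"anchor"` (the trait of a
randomly drawn taxon, guaranteeing the optimum sits in a realized clade);
the Gaussian filter has width τ = 0.2 trait-SD by default, plus a small
background floor (0.002) admitting transient out-of-clade taxa so the
regional pool stays phylogenetically broad as in real surveys. Per-sample
random occupancy (0.6) and lognormal jitter (sd 0.3) produce the
membership turnover that βMNTD measures. Under these defaults a shared
optimum yields median βNTI < −2 in most seeds (median over 10 seeds
≈ −2.5 at 30 samples × 200 taxa), divergent optima yield strongly
positive between-group βNTI, and τ → ∞ reduces exactly to neutral
weighting.

**Yule trees** (`simulate_yule_tree`). Pure-birth topology; ultrametric
branch lengths from the birth process's waiting times, or iid exponential
lengths (mean 0.1) otherwise. Ultrametric trees are the right substrate
for trait-conservation simulations; the exponential option gives generic
branch-length variation for invariance tests.

None of the generators model chimeras, PCR/primer bias, contamination,
compositional spike-ins, or read-level error, so passing tests demonstrate
statistical behaviour of the estimators under their intended generating
processes — not robustness to sequencing artefacts.

## Pipeline

Stages run as enterotype → diversity → differential → network → assembly
→ niche → association; each stage's seed derives from the global seed and
the stage name (CRC-hashed), so toggling one stage never shifts another's
randomness, and the JSON report (floats rounded to 10 decimals, keys
sorted) is byte-identical across runs of the same config. Stage failures
abort with the stage name; completed stages' outputs and a manifest are
retained. Default thresholds are the field-standard values wired through
`PipelineConfig` (prevalence 0.30, mean abundance 10⁻⁴, ρ 0.6, q 0.05,
LDA 2.5, α 0.05, k 2–6, 999/1000 permutations, 70/30 split).

Problem sizes used in the test suite — 97 × ~2000 end-to-end fixture,
50-sample × 300-taxon neutral recoveries, 30-sample × 200-taxon βNTI
calibrations, 200-replicate type-I calibrations at 99 permutations — were
chosen so the full suite exercises every calibration claim at meaningful
scale while remaining comfortable to run locally.

## Known limitations

* LEfSe scores are threshold-compatible, not numerically identical to the
  original tool (no subclass stage).
* Spearman networks ignore compositionality (no SparCC/SPIEC-EASI
  correction) — deliberate, to match the plain-Spearman construction the
  thresholds come from.
* The NCM fit inherits the Sloan diffusion approximation's mild upward
  bias in m at large migration rates (see above).
* βNTI at a few hundred taxa has intrinsically limited power; strongly
  negative medians require genuinely deep trait conservation.
* PERMDISP's median option uses the coordinate-wise median, not the true
  spatial median.
* Raup–Crick pairs each sample's i-th null with the partner's i-th null;
  n_null controls Monte-Carlo resolution (±2/n_null on the index).
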