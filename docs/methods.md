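# Methods

## The synthetic experiment

The generator emulates a high-pressure aquarium study of a tubeworm
symbiosis: 10 treatments spanning substrate-replete, single-substrate
limiting and no-amendment control conditions, 3 worm replicates each
(30 samples), with two cruise-year labels to mirror a two-expedition
design.  Treatments are described by the state of four substrates
(sulfide, oxygen, nitrate, hydrogen), each `replete`, `limiting` or
`absent`; binary condition coding maps replete → 1 and everything else → 0.

Counts are negative binomial via a gamma–Poisson mixture with a
gene-shared dispersion φ (default 0.05; Var = µ + φµ²), the standard bulk
RNA-seq noise model and the one the TMM/precision-weight stack assumes.
The mean model is

    log µ_gs = baseline_g + loading_g · ME_m(s) + log(libsize_s / mean libsize)
    ME_m(s)  = Σ_c effect[m,c] · condition_c(s)  (centred)  + N(0, 0.3)

Baselines are uniform on log-counts (2.5–6.5 nats), loadings uniform on
[0.5, 1.0] for module members and 0 outside modules, library sizes uniform
on 0.8–1.2 M reads.  Defaults plant 5 modules × 100 genes in 1,000 genes;
module 0 carries a +2.0 (log-scale) sulfide effect, modules 1–3 track
oxygen/nitrate/hydrogen, and module 4 carries a −2.0 sulfide effect —
an activity that *rises* under sulfide limitation, the signature of the
alternative carbon-fixation pathway the analysis is designed to find.  The
effect size 2.0 corresponds to ~2.9 log₂-fold between replete and limiting
treatments, a strong but realistic transcriptional response for substrate
starvation.  Two 10-gene seed sets ("CBB-like", "rTCA-like") are the
highest-loading members of modules 0 and 4, with zero cross-loading, so
their true first-neighbour sets (their module co-members) are disjoint by
construction.

What the generator does **not** emulate: host/symbiont read competition
(counts are post-mapping), time-course dynamics within a treatment,
aquarium spillover between co-incubated worms, gene-specific dispersions,
and GC/length biases.  Passing tests therefore demonstrate the pipeline's
correctness and its recovery behaviour under the stated noise model, not
performance on real libraries.

Isotope records are the algebraic inverse of the rate equations: a planted
dry-weight rate is converted to a labelled-tissue δ¹³C given the label
strength (default 2.64 atom% ¹³C of the dissolved inorganic carbon), the
incubation length (48 h) and the natural-abundance tissue δ¹³C (−20 ‰ vs
VPDB); per-mille Gaussian noise is added to measured deltas.  Uptake series
invert the flow-through mass balance c_out = c_in − consumption·biomass/flow.

## Normalization and differential expression

CPM filtering keeps genes with CPM > min_cpm (default 1) in ≥ min_samples
(default 3) libraries.  TMM follows the published trimmed-mean-of-M-values
definition: reference column = library whose upper quartile of scaled
counts is closest to the mean upper quartile; per sample, M- and A-values
over genes expressed in both; 30 % trimmed from each M tail and 5 % from
each A tail; factor = 2^(weighted mean M) with inverse asymptotic-variance
weights; factors rescaled to geometric mean 1.  The implementation is
pinned in tests to an independent straight-line oracle.

Log-expression is log₂((count + 0.5)/(libsize·factor + 1)·10⁶) — the 0.5
prior keeps zeros finite at the cost of exact depth-scale invariance (the
residual is O(prior/count)).

Precision weights: gene-wise OLS residual standard deviations are
lowess-smoothed (frac 0.5) on mean log-expression in √sd space; observation
weights are the inverse fourth power of the predicted √sd at each fitted
value.  Sample quality weights are the inverse mean squared standardized
residual per sample, normalized to mean 1 — outlying samples are
down-weighted, never dropped.  Both weight levels are computed and both are
passed to the fit by default; either can be omitted.

The DE fit is gene-wise weighted least squares on a cell-means (one column
per treatment) design; contrasts are pairwise treatment differences, so
coefficients are log₂ fold changes.  Variance moderation estimates the
scaled-F prior (d₀, s₀²) by moments on log s² (trigamma inversion by
Newton iteration); the posterior variance is the usual weighted combination
and moderated t has d₀ + d_g degrees of freedom.  The robust variant of the
hyperparameter estimation is deliberately not implemented; the run report
records this divergence.  BH adjustment is applied within each contrast and
the DE flag is P_adj ≤ 0.05 and |log₂FC| ≥ 1.

## Network construction and modules

The top 2,500 most-variable genes (or all genes, if fewer) enter the
network.  The signed-hybrid adjacency zeroes negative correlations before
raising to β, so anti-correlated modules (the two sulfide modules with
opposite signs) can never be linked — a property the alliance analysis
relies on.  β defaults to 8; `pick_soft_threshold` implements the
scale-free criterion (smallest β with signed R² ≥ 0.8, else the argmax)
for users who prefer a data-driven choice.  The scale-free fit discretizes
connectivity into 10 equal-width bins and regresses log₁₀ p(k) on the
log₁₀ bin mean of k; the R² is signed by the slope so only decreasing
degree distributions score positively.

Modules come from average-linkage clustering of 1 − TOM with a **static**
branch cut (default height 0.99) rather than a dynamic tree cut: the
static variant is fully specified by two parameters (cut height, minimum
size 30) and therefore exactly testable; both are exposed in config.
Clusters below the minimum size become "grey" (unassigned).  Labels are
color names assigned in decreasing size order from a fixed palette so
reruns are comparable.  Eigengenes are the first principal component of
the gene-standardized module submatrix, unit-norm, sign-aligned with the
module mean profile.  Merging is single linkage on 1 − cor(ME) at height
0.25 (the conventional default; no study-specific value exists), so chains
of pairwise-similar modules collapse — documented behaviour, checked by a
hand-traced test.

GS, MM and module–trait statistics are plain Pearson correlations with
asymptotic Student-t p-values; no multiplicity correction is applied to GS
p-values (none is conventional in this procedure) and correlations use the
unweighted log-expression.  Weighted-correlation variants were considered
and rejected: the weight matrix from the DE stage is contrast-specific and
would make the network depend on the chosen comparisons.

## Hubs, neighbourhoods, alliances

Graph thresholding keeps edges with weight strictly above 0.05 (TOM by
default; adjacency selectable, recorded in provenance), optionally keeps
only each node's k strongest edges (union over endpoints; off by default,
matching the primary weight+degree reading of the filter chain), and then
removes nodes with degree ≤ 2 *iteratively* until a fixed point — a single
pass can leave nodes violating the strict condition.  An empty result is a
warning, not an error.

MCC enumerates maximal cliques exactly (Bron–Kerbosch with pivoting) and
sums (|C|−1)! per node; a node whose open neighbourhood is edgeless scores
its degree (leaves score 1, isolated nodes 0).  Factorial growth means
scores in dense cores are astronomically large; they are kept as floats
(overflow to `inf` would begin near clique size 170, far beyond the
intended graph sizes) and used only for ranking, with ties broken by degree
then gene ID.  First-neighbour sets exclude the seed genes themselves;
genes present in both seed sets are flagged rather than assigned.
Intersection tables report exclusive (UpSet-style) memberships; pairwise
tables report plain shared counts and Jaccard indices.

## Candidate selection

Strictness follows the printed thresholds exactly: |GS| > 0.2, P ≤ 0.05,
|MM| > 0.8, DE P_adj ≤ 0.05 — boundary cases are pinned one-sided in unit
tests.  MM is evaluated against the gene's own module eigengene (the only
reading under which |MM| > 0.8 is meaningful inside the top modules).  The
reported mean/SD log₂FC averages only comparisons that individually
reached significance.

## Tracer arithmetic

R_standard defaults to the VPDB ratio 0.0111802 and is config-exposed.
Natural abundance per tissue type is the mean δ¹³C of the unlabelled
reference set carried in each record.  The dry-weight rate formula is
implemented verbatim including its ×1,000 factor; the resulting unit
question (the printed "µM ¹³C g⁻¹ h⁻¹" vs the mmol-scale the factor
implies if dry weight were pure carbon) is surfaced in the result metadata
rather than silently resolved, and an optional carbon-content fraction
(default 1.0, off) lets users apply the obvious correction.  Dry weight
cancels algebraically in the dry rate; this is asserted as a property.
The uptake formula includes an explicit flow term: concentrations alone
cannot yield µmol h⁻¹, so flow (l h⁻¹) is a required input.

## Problem sizes and determinism

The default test configuration (1,000 genes × 30 samples, 5 planted
modules; 2,000-gene null and 500-gene power simulations for DE; 20 random
instances for each oracle check) keeps the full suite under ~10 s and the
acceptance script under ~5 s while leaving every recovery margin wide
(ARI ≈ 0.92, neighbour precision ≈ 0.95, candidate recall ≈ 0.99 at the
stated seeds).  All randomness flows through `numpy.random.default_rng`
seeded from a single integer; per-stage seeds are derived by hashing
(seed, stage-name) and recorded in the run report; writers use fixed float
formatting (10 significant digits) so equal-seed runs are byte-diffable.

## Known limitations

Static tree cut tends to absorb a few chance-correlated background genes
into large modules (the ARI cost of ~0.05–0.1 on the default
configuration) and, unlike the dynamic hybrid cut, cannot split nested
branches.  The eBayes implementation omits the robust variant, so a few
hypervariable genes can inflate the variance prior.  Scale-free fitting on
strongly block-structured data is often non-monotone in β — on planted
modules the degree distribution is bimodal, which is why the pipeline
defaults to a fixed β rather than the automatic pick.  Block-wise
decomposition for very large gene sets (> 20k) and consensus networks
across cohorts are out of scope.
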