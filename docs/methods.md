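# Methods

This note documents the statistical models, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Data model and preprocessing

Expression matrices are log2-scale intensities (microarray-like),
features × samples, each feature tagged `mRNA`, `lncRNA` or `miRNA`. The
pipeline assumes values are already normalized and never re-normalizes.
Identifier matching is exact, case-sensitive string equality; no alias
resolution is attempted. Probe-level duplicates are collapsed by the
arithmetic mean of the probe rows (first-occurrence order, idempotent);
a repeated id with conflicting class tags is an error. The mRNA/lncRNA
and miRNA series may have entirely disjoint sample sets; nothing
downstream correlates features across the two series — miRNAs are linked
to targets only through interaction records and direction opposition.

## Differential expression

For feature g with group sizes n₁, n₂ the statistic is
t = Δ / (s̃_g √(1/n₁ + 1/n₂)) with Δ the difference of group means of
log2 values (so Δ is log2 fold change directly). With moderation on
(default), the pooled per-feature variance s_g² (d_g = n₁+n₂−2 df) is
shrunk toward a prior: s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g). The prior
(s₀², d₀) is fitted across features by method of moments on log s_g²
(digamma/trigamma matching of a scaled inverse chi-square); when the
spread of log variances does not exceed chi-square sampling noise, d₀ is
infinite and every variance collapses to s₀². p-values are two-sided
from the t distribution with d₀ + d_g df (normal when d₀ = ∞). With
moderation off, a Welch t with Satterthwaite df is used. Features with
zero variance in both groups get statistic 0 and p 1 with a warning
rather than an error, and are excluded from prior fitting.

Direction calls use strict inequalities — `up` iff log2FC > 1.5 AND
p < 0.01 — on *raw* p-values; no multiplicity adjustment is applied at
this stage, matching the calling rule the pipeline targets. Whether
that rule's p is raw or adjusted was ambiguous in its source; raw is
implemented and documented here.

## ceRNA triplet assembly

Candidates: interaction records (miRNA → lncRNA/mRNA) are kept when both
endpoints are differentially expressed with opposite directions.
Co-expression: for each candidate lncRNA–mRNA pair (L, R) sharing a
miRNA, Spearman ρ and raw p (Pr) are computed over all samples (case and
control pooled — pooling maximizes n and the gate is on association, not
group effect). The permutation null holds R fixed and tests n_perm
random other lncRNAs against it; the pool is every measured,
non-constant lncRNA except L, drawn without replacement when the pool is
at least n_perm and with replacement otherwise. The empirical p is

Pe = (#{Pp ≤ Pr} + 1)/(n_perm + 1),

with a pseudo-count of 1, so Pe lives on the grid {k/(n_perm+1)},
bottoms out at 1/(n_perm+1) (1/1001 at the default n_perm = 1000) and is
uniform on the grid under an exchangeable null (verified by a KS check
in the test suite). A triplet is emitted when both candidate edges exist
and the pair passes ρ > 0.6 and Pe < 0.01 — all inequalities strict, ρ
signed (ceRNA competition predicts positive co-expression; an
anti-correlated pair is evidence against the mechanism, not for it).

Spearman engine: ρ is the Pearson correlation of ranks (tie-aware); p
uses the classical t-approximation on √((n−2)/(1−ρ²)) for n > 7 and an
exact rank-permutation null (conditional on the tie pattern) for n ≤ 7,
where the approximation is poor. The vectorized many-vs-one variant used
for permutation pools is checked against scipy's scalar implementation
in the tests.

## Random walk with restart

Each triplet contributes all three pairwise edges — including the
lncRNA–mRNA edge, since the co-expressed pair is itself an established
relationship in the construction; the miRNA-centric star is the obvious
alternative and would only weaken within-triplet mixing. The union is a
simple undirected graph. W is the degree- (column-) normalized
adjacency; p₀ is uniform over the seed genes present in the network
(absent seeds are dropped with a warning; no overlap at all is an
error). Iteration p ← (1−r)Wp + r p₀ converges geometrically at rate
≤ (1−r); the default tolerance is an L1 change below 1e-10. For graphs
up to 2000 nodes the fixed point is cross-checked against the direct
solve p = r(I − (1−r)W)⁻¹p₀ and a deviation above 1e-6 raises.
Zero-degree columns (impossible for triplet-built graphs, possible for
arbitrary input graphs) redirect their mass to the restart distribution
so probability is conserved. Hubs are the top-k probabilities
(k = 30 default); ties at the k-th value are all included and the
effective k reported — node-order invariant and deterministic.
Unreachable components receive probability 0, which is a valid result,
not an error.

## TF network and drivers

TF→target records are kept when at least one endpoint is a
differentially expressed member of the supplied restriction list (the
more inclusive of the two readings of "related to"; restricting to
DE targets only would be the alternative), both endpoints are measured,
and the expression correlation passes |ρ| ≥ 0.5 with p < 0.05. The
absolute-ρ gate deliberately admits repressive TFs. Drivers are the
top-3 TFs by number of retained targets; ties break by higher mean |ρ|,
then lexicographically, making the ranking deterministic.

## Deconvolution

Cell-type fractions per bulk sample solve min‖Sf − b‖₂ s.t. f ≥ 0
(Lawson–Hanson NNLS) over the marker genes shared between signature and
bulk (at least 50 % of the signature's markers must be present), then
rescale to sum to one; the pre-rescale residual RMSE is reported per
sample. Mixtures are additive on the linear scale, so log2-flagged bulk
is exponentiated first. The stage preserves the contract of
reference-based immune deconvolution (bulk + signature → fractions) with
an ordinary constrained least-squares solver and a user-supplied
signature; no support-vector regression and no bundled reference
signature. Group comparison per cell type: log2 of the ratio of group
mean fractions (pseudo-count 1e-6 guards empty types, and the ±1
comparison lines are read on this log2 scale) and a two-sided Wilcoxon
rank-sum p — exact enumeration when both groups have ≤ 10 samples with
no ties, tie-corrected normal approximation otherwise, without
continuity correction so that perfectly balanced ranks give p = 1
exactly.

## Biomarker evaluation

AUC is computed by the Mann–Whitney identity with half-credit for ties.
Auto-orientation (on by default, as ROC tooling conventionally does)
reports max(AUC, 1−AUC) with a flag, so down-regulated markers score
above 0.5. Empirical ROC only — no smoothing, no confidence intervals,
no DeLong tests. Each feature is evaluated within its own series (the
two series share no samples, so a cross-series ROC is undefined).
Enrichment: one-sided hypergeometric upper-tail p per gene set
(equivalent to one-sided Fisher), query and sets intersected with the
user-declared background; BH q-values are reported across sets but
filtering defaults to raw p since no adjusted threshold is prescribed
for this step.

## Synthetic benchmark

The generator emulates two intensity-array series: background feature
rows are Normal(μ_g, σ²) iid across samples with μ_g ~ Normal(8, 2²)
drawn once per feature; planted differential features add ±δ to case
samples. Defaults — δ = 2.5, σ = 0.5, 10 vs 10 samples in the RNA
series, 12 vs 11 in the miRNA series, 400 mRNAs + 400 lncRNAs + 80
miRNAs, 20 planted triplets, 200 decoy interaction edges, 3 planted hub
TFs (12 targets each) among 50 decoy TFs (4 random targets each) — are
chosen to mirror a small two-series case-control microarray study:
group sizes match the emulated design, and δ/σ gives planted features a
~5-sd standardized effect, comfortably but not trivially above the
|log2FC| > 1.5 call threshold at n = 10. In a planted triplet the
lncRNA row is the mRNA row plus Normal(0, 0.1²) noise, so the pair's
Spearman ρ is near 1 and survives the 0.6 gate with high probability;
hub-TF targets are the TF row (sign-flipped around its mean for a third
of targets) plus Normal(0, 0.5²) noise, giving |ρ| ≈ 0.9. Mixtures:
signature markers are Uniform(8, 16) in their own cell type and
Uniform(0.5, 2) elsewhere; fractions are flat-Dirichlet; bulk noise sd
defaults to 5 % of the mean clean signal, truncated at zero.

What passing tests show: the pipeline recovers exactly the structure its
gates describe, at the stated thresholds, under Gaussian noise with
independent features and no confounding. What they do not show:
robustness to batch effects, correlated background features, probe-level
artifacts, heavy-tailed intensities, signature mis-specification, or
database false positives — real-data properties the generator
deliberately omits. The decoy machinery does exercise the main realistic
failure mode: two same-direction differential features are group-
separated and hence strongly co-expressed in pooled samples, so decoy
edges landing on them can create false triplets; the empirical-p gate
plus the rarity of double decoy hits keeps the observed false-report
rate at a few percent.

## Numerical and reproducibility choices

All simulation randomness flows from one integer seed through
numpy's SeedSequence spawn keys (PCG64 streams), so every artifact is
bit-reproducible for a fixed numpy generation; the pipeline derives
per-stage substreams the same way, which makes single-stage re-runs
reproduce the full-run outputs exactly. Permutation draws in the
co-expression test consume one generator sequentially over pairs sorted
lexicographically, so results are order-independent of the input file.
Problem sizes in the test suite and the acceptance script (50-seed
sweeps at the default generator scale, a 2000-feature null, 100 random
graphs ≤ 30 nodes, 500 uniformity replicates at n_perm = 199) are the
package's chosen benchmark scale: large enough for the rates being
estimated to have small Monte-Carlo error relative to their acceptance
margins, small enough to keep the full suite around a minute.

Known limitations: no covariate adjustment or paired designs in the DE
stage; no heterogeneous multi-layer RWR (all edges weigh equally
regardless of RNA class); enrichment treats gene sets as flat lists;
deconvolution has no absolute mode and no per-sample significance;
identifier namespaces must already agree across all inputs.
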