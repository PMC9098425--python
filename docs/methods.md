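# Methods

This note documents the statistical procedures, the synthetic benchmark,
and the numerical conventions behind `omicsfunnel`, in the order the
pipeline runs them.

## Study design and data model

The pipeline assumes a single-exposure time course: one control group at
time 0 and several post-exposure groups at strictly increasing times
(default `PBS, 2W, 4W, 6W, 10W` in weeks), each with a small number of
biological replicates, profiled on three layers:

* **rna** — non-negative read counts per transcript;
* **protein** — log₂ intensities per protein (missing values allowed);
* **phospho** — log₂ intensities per phosphosite (missing values allowed;
  several sites may map to one gene).

Missing values are carried as an explicit boolean mask (written as `NA`
in TSV), never as a sentinel number; no imputation is performed anywhere.
Sample order is dictated by the sample sheet and matrices are re-indexed
to it, so downstream outputs are deterministic regardless of column order
in the input files.

## Normalization

RNA counts become `log2(count / libsize × 1e6 + 1)` with the library size
taken as the per-sample column sum. This total-count normalization is
simple and test-friendly, but it is *compositional*: when a sizeable
fraction of the transcriptome genuinely rises, every log-CPM is deflated
by the library growth (≈ log₂ of the mean fold-change across genes). The
synthetic benchmark quantifies this effect and the generator defaults
account for it (below); analyses of real data with very large
perturbations may prefer a robust size-factor method upstream.

Protein and phospho matrices are median-centered per sample (the median
over observed values). The typical upstream processing of intensity data
leaves an arbitrary per-sample shift; median centering is the minimal
correction and is recorded in the run report.

## Differential calling (stage D)

Every feature is tested with a classical one-way ANOVA across all groups
(F = MSB/MSW, p from the F upper tail), computed vectorised with the
missing-value mask; a feature needs at least `min_obs_per_group` (default
2) observed values in every group or it is dropped and counted in the
report. Benjamini–Hochberg runs across the tested features *within each
layer*; `D` is the set with adjusted p < α (default 0.05). Degenerate
variance is handled explicitly: MSW = 0 with MSB > 0 reports p = 0, both
zero reports p = 1, and the row carries a `degenerate` flag.

Tukey–Kramer post-hoc comparisons are reported for every group pair:
q = |m̄ᵢ − m̄ⱼ| / √(MSW/2 · (1/nᵢ + 1/nⱼ)), p from the studentized range
distribution with k groups and df = N − k. The exact tail costs
milliseconds per evaluation (numerical quadrature), so the bulk screening
path evaluates it through a monotone PCHIP interpolant of log-sf on a
768-point q grid per (k, df); the absolute error is below 1e-6 (asserted
in the tests), and the single-feature `tukey_hsd` operation always uses
the exact distribution. The funnel itself consumes only the omnibus
calls; the pairwise columns are descriptive output.

Design choice: one engine (ANOVA on normalized values) serves all three
layers, rather than a negative-binomial GLM for counts and ANOVA for
intensities. The funnel only consumes the per-layer significance sets, a
single well-tested engine keeps the multiplicity ledger uniform, and the
substitution is listed in the run report's deviations section. Similarly,
`D` is defined by the omnibus test rather than a union of pairwise
contrasts: both play the same screening role, and the omnibus definition
needs one BH pass instead of ten.

## Trend clustering (stage C)

The group means of each differential feature, in time order, are row
standardized to mean 0 / sample sd 1 (n−1 denominator); constant profiles
cannot be standardized and are dropped with a log entry. Fuzzy c-means
then minimises Σᵢₖ uᵢₖ^m d²ᵢₖ by alternating

* memberships uᵢₖ = 1 / Σⱼ (dᵢₖ/dᵢⱼ)^(2/(m−1)) (a point coincident with
  one or more centroids splits its membership equally among them), and
* centroids cₖ = Σᵢ uᵢₖ^m xᵢ / Σᵢ uᵢₖ^m,

until the objective improves by less than `tol` (1e-6) or `max_iter`
(500) is reached, taking the best of `restarts` (5) initializations with
centroids drawn from distinct data rows. The objective is asserted
non-increasing on every run. Defaults: K = 6 clusters (a conventional
choice for five-point omics time courses, fixed rather than selected
automatically) and fuzzifier m = 1.25 — with standardized profiles in few
dimensions, m = 2 drifts toward uniform memberships, while values near
1.25 give sharp but still soft partitions; both are configurable and
recorded in the report.

A cluster is labelled **up** when Kendall τ between its centroid and the
group times is ≥ `trend_tau` (0.6) *and* the net change (last − first) is
positive; **down** symmetrically; anything else (transient bumps,
oscillations) is **other**. τ uses the τ-a pair-count convention — tied
pairs count toward neither direction — which conservatively pushes
flat-ish centroids to "other". Core members are features whose maximum
membership reaches `membership_cutoff` (0.5); with a cutoff above 0.5 a
feature is core in at most one cluster, which makes the set C
well-defined. Ties in the membership argmax break toward the lowest
cluster index.

Clustering runs on the differential features only, not the whole
detected matrix: the trends of interest are by construction trends among
features that change.

## Enrichment (stage P inputs)

Feature lists are mapped to gene symbols through the user-supplied id
map; multiple phosphosites collapse to one gene (set semantics), and
unmapped features are reported, not fatal. Over-representation uses the
one-sided hypergeometric upper tail P(X ≥ k) with the universe defined as
*all genes quantified in the layer* (standard ORA background practice —
the background of a proprietary pathway tool is not reproducible, a
user-supplied GMT plus the quantified universe is). Sets are intersected
with the universe and kept when `min_set_size` ≤ K ≤ `max_set_size`
(5/500); BH runs within each list across retained sets.

The multi-list link computation reports, between ≥ 2 named gene lists,
the genes shared by several lists ("same-feature" links) and the
cross-list gene pairs co-annotated to at least one common set
("shared-term" links) — a text representation of the usual multi-omics
chord diagram; rendering is out of scope.

## Pathway intersection and weighted p (stage P)

A pathway enters P when its BH-adjusted enrichment p is below α in all
three layers, each layer represented by the union of core features of
its direction-labelled clusters. P is then ranked by the weighted
p-value W = p₍rna₎ · p₍prot₎ · p₍phos₎ built from *raw* per-layer p's
(admission is by adjusted p, ranking by raw product; when a layer
contributes several lists the minimum raw p represents it). Ties break
lexicographically on set id. W is a ranking score, not a calibrated
p-value — multiplying dependent p's has no null guarantee — and is
documented as such. Ranking by W is verified against ranking by Σ log p
for numerical stability.

## Funnel tail and drug screen (F, f, T)

F collects the genes of the top `top_k_pathways` (10) pathways by W that
appear in at least one layer's C (membership in an up-trending core
cluster of *some* layer keeps F tied to observed upregulation without
requiring all three layers to cluster the gene). f keeps the F genes
with at least one phosphosite at adjusted p < α whose direction (sign of
last-time mean − control mean) matches the funnel direction. T keeps the
f genes with a matching drug-table row: inhibitors for the up direction,
activators for down, approved-only by default. The down-direction funnel
is computed and reported but screens no drugs unless explicitly asked —
activating a downregulated target is rarely a viable repurposing
strategy. Candidates are ranked by (best W among containing pathways,
|phospho effect| descending, gene name).

## Synthetic benchmark

The generator emulates the study design above: five groups × 3
replicates, 1000 genes, each gene carrying one temporal archetype shared
across layers — up (15%), down (15%), transient (10%, rise to mid-course
and return), flat (the rest) — with piecewise-linear effect curves in
scaled time. Layer mechanics:

* RNA: counts ~ NB with mean μ_g·2^(shape(t)·e_g)·ℓ_s, μ_g log-uniform
  on [20, 2000], dispersion 0.1 (var = μ + 0.1μ²), per-sample library
  factors ℓ_s log-uniform within 2×;
* protein: baseline + shape(t)·e_g + N(0, 0.25) on log₂ scale, plus a
  per-sample shift (sd 0.3) that median centering must remove;
* phospho: as protein with 1–3 sites per gene, 10% values missing
  completely at random, and an extra +0.5 effect on driver-gene sites.

Five driver genes are planted: up-archetype, members of one "active"
pathway, and an approved-inhibitor row in the drug table. The drug table
also contains 50 decoy genes with random modality/approval. 50 pathways
of size 10–40 sample genes uniformly, except the active pathway, which
is pinned at the top of the size range with 80% up-archetype members
(drivers included).

Effect sizes e_g are drawn uniform on [1.75, 2.0] log₂ units at the
curve's peak. The floor is deliberately high: with 3 replicates the
count layer's ANOVA has df₂ = 10, NB dispersion 0.1 puts the within-group
sd near 0.5 on the log₂-CPM scale, and the compositional deflation of
total-count normalization removes another ≈ 0.4 from realized up-gene
spans — planted effects much below the 2.0 cap are simply not detectable
in counts at this design size, and the benchmark's purpose is recovery of
a clearly planted signal, not a power study. The same reasoning fixed the
active pathway's composition and size. These defaults were set from the
power analysis while designing the generator and then frozen.

What the generator does *not* emulate: intensity-dependent (MNAR)
missingness, batch structure beyond a per-sample shift, correlated genes
within pathways (decoy pathways are annotation-only), count overdispersion
heterogeneity, and paired designs. Recovery results on this benchmark
therefore demonstrate correctness of the machinery under a clean planted
model, not expected performance on real tissue time courses.

## Determinism and numerical conventions

A single master seed in the config drives every random draw; per-layer
clustering seeds derive from it through named `SeedSequence` streams. All
JSON bodies have sorted keys and no timestamps, so identical config +
seed reproduce byte-identical traces and reports (asserted in the tests).
Stages hand off through files; each work directory materializes its
config, and every later stage verifies the config digest before using
upstream outputs. p-values are clipped to [0, 1]; BH uses the step-up
formula via statsmodels with a brute-force oracle in the tests;
hypergeometric tails come from scipy with an exhaustive-enumeration
oracle for small universes.

## Known limitations

* Total-count CPM is compositionally biased under large perturbations
  (quantified above); DESeq2-style size factors are out of scope.
* No moderated/empirical-Bayes variance: with 2–3 replicates per group
  the per-feature ANOVA is noisy, and the benchmark compensates with
  strong planted effects rather than shrinkage.
* W is a heuristic ranking score across dependent tests.
* The gene-set collection and drug–target table are user-supplied local
  files; no live database access, no kinase-substrate inference.
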