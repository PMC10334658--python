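# Methods

## Scope and data model

The pipeline consumes taxon-by-sample feature tables (TSV; BIOM 1.0
JSON accepted) with per-sample metadata (`sample_id`, `dataset`,
`group ∈ {case, control}`). Tables are kept in one of two modes:
`counts` (non-negative integers) or `relative` (per-sample proportions
summing to 1 within 1e-9). Collapsing to a taxonomic rank happens on
counts (exact integer conservation of per-sample totals); taxa
unassigned at the rank are pooled under a single `unclassified` label
by default (`drop_unclassified` removes them), and names duplicated
under different parents are disambiguated with the full lineage prefix.

Merging restricts every table to the *intersection* of taxon sets and
concatenates samples. By default the surviving proportions are **not**
renormalized — each sample keeps its original scale, so values remain
interpretable as fractions of the whole community; `renormalize=True`
re-closes columns over the shared taxa. Both behaviours are provided
because either reading of "merged on shared taxa" is defensible;
downstream alpha-diversity indices always re-close each sample's
retained proportions before computing entropy, so the choice affects
Bray–Curtis and correlation magnitudes only marginally.

## Diversity

* Shannon entropy uses natural log (nats) with a configurable base;
  Simpson is reported in the Gini–Simpson form 1 − Σp², with the
  inverse form available. Both are permutation-invariant in taxa.
* Bray–Curtis is computed on relative abundances via
  `scipy.spatial.distance.pdist`.
* PCoA is classical MDS: B = −½·J·D²·J, eigendecomposition, coordinates
  from positive eigenvalues only. Negative eigenvalues (Bray–Curtis is
  not Euclidean-embeddable) are reported but excluded from coordinates
  and explained-variance proportions; no Lingoes/Cailliez correction is
  applied.
* PERMANOVA uses SS_T = Σ_{j<k} d²_jk/n and the analogous within-group
  sum; p = (#{F_perm ≥ F_obs}+1)/(nperm+1) over seeded label
  permutations (default 999). The permutation loop is implemented
  in-package so a seed fully determines the result; the pseudo-F agrees
  with scikit-bio's to machine precision (asserted in tests).
* Beta-dispersion embeds samples on all positive PCoA axes and measures
  each sample's distance to its group centroid (centroid variant; the
  spatial-median variant is out of scope), compared by one-way ANOVA.
  Single-sample groups contribute zero dispersion with a warning.

## Differential abundance

Per taxon, a two-sided Wilcoxon rank-sum test between case and control
relative abundances: exact enumeration when n₁+n₂ ≤ 12 without ties,
otherwise the normal approximation with midranks, tie correction and
continuity correction (delegated to `scipy.stats.mannwhitneyu`; the
exact branch is verified against brute-force label enumeration). The
Shapiro–Wilk screen is reported but never gates the rank-sum test.
BH adjustment q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j is applied over all taxa at one
taxonomic level (one family per level; no cross-level pooling), with
significance at q < 0.05. Zero-inflated taxa are tested as-is; an
optional prevalence filter exists but defaults to off. A taxon constant
across all samples is assigned p = 1.

## Taxon modules (DBSCAN)

Points are taxa; coordinates are their relative abundances across all
samples. With `scale=true` each profile is standardized, which makes
squared Euclidean distance proportional to one minus the profile
correlation — the recommended setting when modules are understood as
groups of co-varying taxa rather than taxa of similar absolute
abundance. DBSCAN is implemented in-package: a core point has
≥ `min_pts` neighbours within `eps` (self included), clusters are
maximal density-connected sets, and border points join the first
cluster that discovers them, with rows processed in sorted taxon order
so results are reproducible. Because no eps/minPts/scaling conventions
are standard for this use, all three are explicit configuration with
defaults `min_pts = 4` and `eps` from the knee (maximum deviation below
the chord) of the sorted (min_pts−1)-NN distance profile. Modules are
lettered A, B, C, … in discovery order.

## Co-occurrence and rewiring

Within each condition, all unordered pairs of non-constant taxa are
tested: r = Pearson correlation of relative abundances pooled across
datasets, p from Student-t with n−2 df. "Existence" of an interaction
is its significance flag — no magnitude cutoff — with two modes:
raw p < α (default α = 0.05, matching dense paper-style networks) or
BH over all pairs at the level (`edge_adjust: BH`). Non-significant
coefficients are retained in storage but treated as zero downstream.

Differential classification per pair: significant in case only →
gained; in control only → lost; in both with opposite signs →
changed direction. A sign flip of a non-significant correlation is
treated as noise, so changed-direction requires significance in both
conditions. The three classes partition the rewired edge set, and
swapping the input networks exchanges gained and lost while fixing
changed-direction (asserted as an invariant). Rewiring degree is the
count of incident rewired edges per node.

Centralities are computed on the rewired graph, all classes as
undirected unweighted edges, via networkx with Cytoscape conventions:
betweenness normalized by (n−1)(n−2)/2, closeness component-local
(reciprocal mean shortest-path distance to reachable nodes), local
clustering 2·links/(k(k−1)), neighborhood connectivity = mean neighbour
degree. All four are verified against brute-force references computed
straight from the definitions. Hub cutoffs: degree ≥ 4 (phylum),
> 15 (genus); no standard family cutoff exists, so the family level
requires explicit configuration.

## Synthetic data generator

Generative family: logistic-normal/multinomial. Per sample,
z ~ MVN(μ_group, diag(σ)·C_group·diag(σ)), proportions = softmax(z),
counts ~ Multinomial(depth, proportions). A Dirichlet-multinomial
cannot plant arbitrary pairwise correlation signs, which is the whole
point here. Per-dataset random streams derive from the master seed and
the dataset index, so any dataset regenerates reproducibly; depths are
log-uniform per sample within a per-dataset range.

The study-shaped default (`make_paper_like_spec`) emulates four
datasets with case/control sizes scaled from (245/231, 50/207, 27/26,
25/24) — 347 cases and 488 controls at full scale (per-dataset
round-half-away-from-zero) — with 64 genera, nominal depth 50 000
(spread factor 2), 10 case-only and 10 control-only latent pairs at
|r| = 0.8 (alternating signs), 2 sign-flipped pairs, 4 modules of 5
taxa at intra-module latent ρ = 0.9, and 8 differential taxa with ±1.0
latent log-mean shifts.

Free parameters were calibrated once, against the generator's own
contract (planted correlations must dominate unplanted ones and be
recoverable end-to-end), with the following rationale:

* **σ = 0.6 for all taxa.** The observed correlation of two lognormal
  variables with latent correlation ρ is (e^{ρσ²}−1)/(e^{σ²}−1): at
  σ = 0.6 a planted ρ = 0.8 appears as r ≈ 0.70, at σ = 0.8 only
  ≈ 0.64, and heavier tails additionally inflate the sampling
  variance of Pearson r through leverage points. Homogeneous σ keeps
  the latent→observed mapping transparent.
* **Baseline log-means ~ N(0, 0.4), correlated blocks down-weighted by
  −1 in log-mean.** Softmax closure induces correlation between
  latently independent taxa proportional to the denominator's
  concentration (≈ Herfindahl of taxon weights, amplified when
  correlated blocks hold large weight). Keeping the denominator spread
  across many, mostly independent taxa keeps closure correlations an
  order of magnitude below the planted signal. This is a deliberate
  generator property: ground truth is defined in latent space, and a
  generator whose compositional artifacts rival the planted structure
  cannot define ground truth meaningfully.

What the generator does *not* emulate: sequencing error, chimeras,
taxonomy misassignment, batch effects beyond depth, zero-inflation
beyond what the multinomial induces, and real ecological network
topology (planted edges are disjoint pairs, not scale-free graphs).
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not performance on real
16S data, where compositional closure, sparsity and Pearson's
outlier-sensitivity are harsher.

## Evaluation sizes and numerical choices

The recovery measurements (tests and `scripts/acceptance.py`) run at
scale 0.4 — 139 cases / 195 controls, matching the regime where the
planted effects are designed to be detectable — over 10–20 replicate
seeds; edge-recovery F1 is measured on a spec with only the
condition-specific pairs planted (zero latent correlation elsewhere),
the condition the recovery contract states, and with BH-adjusted edge
significance: with ~2 000 taxon pairs per level, raw per-pair α = 0.05
would admit ≈ 90 false rewired edges per condition by construction, so
the raw mode — kept as the default for descriptive, paper-style dense
networks — is not meaningful for truth recovery. PERMANOVA calibration
uses 1 000 null replicates of 12 samples with 199 permutations.

Degenerate inputs are handled explicitly: all-zero samples are rejected
before normalization, condition-constant taxa are excluded from
correlation testing with a logged notice, identical-everywhere taxa get
p = 1, ANOVA on exactly equal dispersions returns p = 1, and the
k-NN-knee eps falls back to the largest profile value when the profile
is flat. Ties in DBSCAN border assignment are broken by fixed sorted
point order; module letters follow discovery order.

## Known limitations

Pearson correlation on relative abundances is not
compositionally-aware (SparCC/SPIEC-EASI-style estimators are out of
scope by design); rewiring classes depend on significance thresholds,
so near-threshold edges can flip class between reruns of a study at
different sample sizes; the family-level hub cutoff is user-defined;
and PCoA axes are reported without correction for negative
eigenvalues.
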