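# Methods

This note documents the models behind each stage, the parameters that
matter, the design choices made where the procedure is genuinely open,
and what the synthetic data do and do not establish about real screens.

## Feature quality control

**Reproducibility filter.** For each feature and each seeding density,
one vector per biological replicate is formed, indexed by construct
(targeting and non-targeting constructs alike; empty wells excluded),
and all C(R,2) replicate pairs are tested with the sample Pearson
coefficient and its exact two-sided p (t-transform on n−2 df).  A
feature is removed if *any* pair has r < 0 or p > α (default 0.05).
This "any-pair" reading is the most conservative interpretation of a
per-guide pairwise test battery — a single discordant replicate already
breaks reproducibility; a pooled "mean" rule is available behind
`rule="mean"`.  When two densities are present a feature must pass in
both, since densities are distinct biological conditions.  Constant
replicate vectors make the correlation undefined and count as
non-reproducible.

**Guide reduction and Z-normalization.**  Wells reduce to one value per
construct (mean over its replicate wells, densities pooled — the
well→guide reduction is not dictated by the assay, and the mean is the
minimum-variance choice for symmetric noise).  Each feature is then
Z-normalized across *all* guide rows, controls included; controls are
deliberately not used as the centering reference, so a screen where
most perturbations are null centers on the null behavior itself.

**Redundancy pruning.**  Greedy pruning of the absolute correlation
matrix at cutoff 0.9: repeatedly take the worst remaining pair above
the cutoff and drop the member with the larger mean absolute
correlation to everything still retained (ties drop the later column in
header order, for determinism).  The retained set provably contains no
pair above the cutoff, which is asserted on every run.  This is the
classic "findCorrelation"-style heuristic; it does not minimize the
number of removals globally, but it is deterministic and
order-insensitive given the header.

## Gene profiles

A gene's profile is the per-feature **median** of its guides' Z-scores
(median of 3 = middle value; of 2 = mean).  Guides are not weighted by
modification efficiency — the screen analysis applies none, and the
median already limits the influence of one failed guide.  Non-targeting
guides collapse into a single pseudo-row.  Extreme features are ranked
within feature by |Z| (rank 1 = most extreme) above a threshold of 2.5,
the top-percentile convention for ~133 perturbations; a signed mode
exists for dispersion-like features where the direction matters.

## Clustering and bootstrap support

**Ward.D2.**  Agglomeration runs the Lance–Williams update on *squared*
Euclidean distances and reports merge heights on the original scale;
heights are therefore monotone, which is asserted.  Ties on the minimal
Ward distance merge the pair whose smallest original leaf index is
least — real-data ties are measure-zero, but the rule makes synthetic
edge cases reproducible.  The implementation is validated against both
a naive O(n³) re-agglomeration and scipy's `linkage(..., 'ward')` for
all small instances.

**Multiscale bootstrap.**  Features (columns) are the resampled
observations — they are the evidence supporting gene–gene relationships,
and resampling them asks how strongly the feature set as a whole
determines each cluster.  At each scale r ∈ {0.5, …, 1.4}, round(r·m)
of the m features are drawn with replacement, profiles are re-clustered,
and each full-data node counts the fraction of bootstrap trees
containing exactly its leaf set, BP(r), clipped to
[1/(B+1), 1−1/(B+1)].  The probit-transformed values
ψ(r) = Φ⁻¹(1−BP(r)) follow the signed-distance/curvature model
ψ(r) = v·√r + c/√r, fit by weighted least squares with binomial
variance weights w = B·φ(ψ)²/(BP(1−BP)); the approximately-unbiased
support is AU = 1 − Φ(v−c) and the plain bootstrap probability is
BP(1).  "Resampling p" is 1 − AU.  Default replication is 1,000 per
scale × 10 scales = 10,000 trees total; the analysis drivers use 250
per scale, which is ample for the planted-structure data they run on.

*Degenerate fits.*  When fewer than 3 scales have BP strictly inside
(0,1) the curve is unidentifiable; the node then reports the pooled BP
across all replications as its support, flagged via `fit_ok=False` and
a note.  A cluster present in every bootstrap tree at every scale thus
reports AU = 1 exactly, which is the desired reading for perfectly
stable clusters.

**Branch cut.**  k = 3 follows the three-major-branches structure of
this screen family (control-like, lethal, lipo).  Cluster ids are
ordered by the smallest contained leaf index so runs are comparable.
Control pseudo-rows are clustered by default (they make branch identity
interpretable); the cut can also run on genes only.

## Enrichment

For each (branch, gene set): the 2×2 table over the gene universe
(controls excluded), the sample cross-product odds ratio ad/bc with the
Haldane–Anscombe +0.5 correction when a cell is empty (flagged), and
the hypergeometric upper tail P(X ≥ a) summed in log space.  The
conditional-MLE odds ratio was rejected in favor of the closed form:
reproducible, and indistinguishable at screen-scale counts.  p-values
are raw, matching how such clusters are annotated; a Benjamini–Hochberg
column is emitted for convenience but drives no decision.

## Indel odds ratios

Alleles parse from compact descriptors ("−16:32D" = 32 bp deletion at
offset −16, comma-separated ops, WT/SNV for no indel).  An allele is
disruptive iff any *single* op is strictly longer than 3 bp — net
length across ops is deliberately not used, since a 2 bp insertion plus
2 bp deletion does not imply a disrupted site.  Reads (not alleles) are
the counting unit.  The log odds ratio carries the closed-form Wald SE
√(1/a+1/b+1/c+1/d); a grouped IRLS logistic fit is retained as a
cross-check because the two coincide for a saturated 2×2 model (asserted
to 1e−6).  Zero cells require an explicit Haldane correction flag.

## Biophysical utilities

The AFM spherical-cap volume V = (πh/6)(3r² + h²) is validated against
numerical disk integration of the cap cross-sections (1e−6 relative on
an (h, r) grid).  The mass-based prediction V = (M₀/N₀)(V₁ + dV₂) uses
the exact SI Avogadro number, V₁ = 0.74 cm³/g, V₂ = 1 cm³/g, hydration
d = 0.4 g/g, with the cm³→nm³ conversion (×10²¹) inside the function;
inputs are in Da.  "Peak ± SEM" of a volume histogram is the
maximum-likelihood Gaussian mean ± sample SD/√n — a histogram-mode
estimate was rejected as bin-dependent.  qPCR fold change is plain
2^−ΔΔCT without efficiency correction.

## Synthetic data: what it emulates, and what it does not

The screen generator plants exactly the structure the pipeline is built
to detect, with defaults chosen as a realistic rendering of this assay
class (chosen once, before any tuning against outcomes):

- **Design**: 133 genes × 3 guides + 25 non-targeting, 4 replicates ×
  2 densities, 425 features (148 base + 249 redundant + 28 noise,
  mirroring the screen bookkeeping this family of analyses reports).
- **Base features**: block-correlated Gaussians (blocks: cell_number
  ~8%, lipid_droplet ~27%, texture ~32%, other; within-block
  correlation 0.2) with a construct-level component (SD 1) shared by a
  construct's wells — the source of replicate reproducibility — plus
  per-well noise (SD 0.5, i.e. replicate correlation ≈ 0.8 for null
  features).
- **Group effects** in units of the construct-level SD, scaled per
  guide by a modification efficiency drawn uniform [0.7, 1.0] (the
  efficiency range this assay family reports): lethal = −4 on
  cell-number and −2 on lipid-droplet blocks (cells die, little lipid);
  lipo = −3 on lipid with −0.3 on cell number (lipid lost, cells
  near-normal); control-like = null.  Group sizes default to
  106/13/14.
- **Noise features**: independent per well, hence no inter-replicate
  concordance.  **Redundant features**: a base feature's well values
  plus noise calibrated to a population correlation of 0.95.
- **Sorted-bin alleles**: Dirichlet allele frequencies, multinomial
  reads, each read assigned to the low bin by a Bernoulli whose odds
  are `true_or`-fold higher for disruptive alleles — the simplest
  generative model whose population 2×2 odds ratio equals `true_or`
  exactly.  Disruptive indel lengths are uniform on 4–32 bp,
  non-disruptive on 0–3 bp (0 = SNV/WT).
- An optional per-plate additive effect (default off) exists because
  such screens randomize plate positions rather than model them; the
  pipeline deliberately applies no batch correction either.

What passing tests on these data show: the filters remove exactly what
they target, aggregation and clustering recover planted group structure
at realistic effect sizes, estimators are unbiased with calibrated
intervals.  What they do not show: robustness to plate/illumination
artifacts, non-Gaussian feature distributions, heteroskedastic feature
scales, partially effective guides with off-target profiles, or
missing wells — real screens need those checked separately.

## Numerical choices and limitations

- Pearson p-values use the exact t-transform; n < 3 or constant input
  is an error (mapped to non-reproducibility by the filter).
- Z-normalization uses the sample SD (ddof = 1) and refuses constant
  columns rather than imputing.
- The bootstrap scale entering the probit fit is the *achieved*
  fraction round(r·m)/m, not the nominal r.
- Problem sizes in the test-suite recovery studies (20 seeds at the
  full default design; 50 odds-ratio replicates at 5×10⁴ reads/bin;
  1,000 coverage replicates at 2×10³ reads/bin) were chosen as the
  smallest giving stable Monte-Carlo verdicts for the tolerances
  checked.
- The Newick export halves merge heights so root-to-leaf depth equals
  half the final merge height (ultrametric rendering); trees with
  branch-length semantics other than dendrogram heights are out of
  scope.
- Wald intervals are first-order; at very low read counts (cells < ~5)
  profile-likelihood or exact intervals would be preferable and are not
  implemented.
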