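# Methods

## The model

BGC typing treats a field survey as two matrices over a shared, ordered set
of sampling points: a community matrix `X` (OTU relative abundances, fused
from up to three amplicon domains) and a chemicals matrix `Y` (element
concentrations, FT-IR integrals, NMR bucket integrals, fused from up to
three instrument blocks). The working assumption is that a small number of
latent environmental conditions drive monotone co-fluctuation between groups
of organisms and groups of chemical variables; Spearman correlation is used
throughout so that only monotone association matters, not the (arbitrary)
units or response shapes of the instruments.

The unit of analysis after Filtration is the **correlation matrix** `R`
(filtered OTUs × all chemical variables). An OTU's row of `R` is its
*chemical signature*; BGC types are clusters of signatures. Because squared
Euclidean k-means is invariant to rotation and translation, clustering the
rows of `R` is exactly equivalent to clustering all mean-centred PCA scores,
which the test suite asserts; a two-component score space
(`cluster_space="pc_scores_2d"`) is offered for reproducing delimitations
drawn on a PC1/PC2 plot, and both choices are recorded in the run manifest.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.70 | min \|ρ\| (inclusive) for an OTU to be retained; applied to its best chemical partner |
| `k_max` | 15 | largest cluster count evaluated on the WCSS curve |
| `stdevp_cut` | 0.20 | pairwise population-SD cut for chemical-variable extraction |
| `n_init` | 50 | k-means restarts (k-means++ seeding), best inertia kept |
| `centering` | mean | PCA column centring of `R`; no variance scaling, since all entries share the correlation scale |
| `singleton_min_total` | 2 | min total reads over all sampling points |

The first three defaults are the method's published operating points and are
asserted as config defaults in the tests. Undefined correlations (constant
trajectories) are masked and can never satisfy the threshold — a feature
read once, or a flat chemical variable, carries no trend.

## Numerical choices

* **Spearman ρ** is the Pearson correlation of average (fractional) ranks;
  ties get the mean of the ranks they span. The implementation (vectorised
  rank-then-dot-product) is checked against a brute-force oracle on all
  length-4 permutation pairs and random tied vectors, and against
  `scipy.stats.spearmanr` pairwise.
* **Elbow selection** maximises the discrete second difference
  `w[k−1] − 2w[k] + w[k+1]` over interior k; ties break toward smaller k,
  and a curve with no positive second difference (relative to the curve
  scale, tol 1e-9) is flagged "no elbow" with a warning. The full profile is
  always reported and the CLI accepts `--k` to override — inflexion reading
  is ultimately a judgement call.
* **PCA** is computed by SVD; component signs are fixed so each loading
  column's largest-magnitude entry is positive. Before the chemical-profile
  comparison the explaining PC's loading vector is additionally sign-aligned
  to the type's mean-correlation vector, because the extraction outcome must
  not depend on an arbitrary eigenvector sign.
* **Unit variance without centring** is division by the population RMS
  `sqrt(mean(v²))` (the non-central second moment), so the scaled vector has
  mean square exactly 1 and keeps its zero point; a centred-SD variant
  (`scaling="sd"`) is exposed for sensitivity analysis.
* **Cluster labels** are renumbered by descending cluster size (ties by
  smallest member id) so "BGC type 1" is stable across runs and seeds.
* **Tables are parsed with correctly-rounded float conversion** and written
  with 17 significant digits, so a TSV write/read round-trip is bit-exact.
* The explaining PC per type is the one (of PC1/PC2) with the larger
  absolute mean member score; an exact tie falls back to PC1 with a warning.

## The synthetic survey generator

`bgctype.synth` emulates the *shape* of a paddy-field style survey: 14
sampling points, three amplicon domains, three chemical blocks, 4 planted
BGC types of 25 OTUs and 5 chemical variables each, plus 20 uncorrelated
OTUs, 5 singleton OTUs, 6 uncorrelated chemical variables, latent-scale
noise SD 0.1, and multinomial read sampling at depth 50,000 per sampling
point (so relative-abundance normalisation, and its compositional coupling,
are real).

Design choices that required judgement:

* **Paired axes.** The four types sit pairwise on two orthogonal
  environmental gradients, the two types of an axis having factors with
  sample correlation −r (defaults r = 0.45 and 0.18). This is the cross-like
  score geometry of real BGC typing — two types at opposite ends of PC1, two
  at opposite ends of PC2, one axis more contrasted than the other. The
  partial (not full) anti-correlation matters twice: with r = 1 a type's
  mean-correlation curve is exactly proportional to the PC loading curve and
  the STDEVP rule extracts nothing, while with r = 0 (independent factors)
  the sign rule cannot separate a type from its axis partner. The distinct
  r values also separate the PC1/PC2 eigenvalues, so the loading directions
  are numerically stable instead of rotating freely inside a degenerate
  eigenspace.
* **Conditioned latent draw.** With only 14 sampling points, two generic
  orthogonal Gaussian vectors still show chance Spearman correlation of
  order 1/√13 ≈ 0.28 — enough to contaminate planted "uncorrelated"
  structure. Since the generator's job is to *plant* a known truth, the
  latent draw is rejection-sampled until cross-axis rank correlations are
  ≤ 0.025 and within-pair rank correlations are within 0.05 of −r; null
  features are likewise redrawn until their chance association with every
  factor is ≤ 0.15 (caps checked by the tests). Measurement noise then
  enters explicitly through `noise_sd`.
* **Constant-total background taxon.** Each domain includes one background
  OTU absorbing the remaining expected read mass, keeping the per-point
  total constant so that every planted OTU's relative abundance is monotone
  in its factor. Ecologically this is a dominant resident taxon; numerically
  it prevents compositional closure from distorting planted correlations
  (with it, the zero-noise within-block Spearman is ≥ 0.95 at depth 1e5,
  which the tests assert).

What the generator does **not** emulate: overdispersed (non-multinomial)
sequencing noise, sparsity/zero-inflation of real OTU tables, correlated
chemistry within an instrument block beyond the planted gradients, spatial
autocorrelation between sampling points, and drifting baselines in spectra.
Passing recovery tests therefore demonstrates correctness of the pipeline's
logic under the stated model, not robustness to every artefact of real
surveys.

## Problem sizes used in the checks

The recovery studies run the full pipeline on 20 independently generated
surveys at the defaults above (~125 OTU rows after filtering, 26 chemical
variables, k-means with 20 restarts for k = 1…15); the WCSS exhaustive
oracle uses 6-point instances where all partitions can be enumerated; the
Spearman oracle covers all 576 length-4 permutation pairs plus 200 random
tied vectors. These sizes make every check a from-scratch computation of the
quantity it reports.

## Known limitations

* The STDEVP extraction rule measures *disagreement* between a type's mean
  correlation and a global PC direction; for a perfectly symmetric pair of
  clusters it approaches zero everywhere and extracts nothing. Real surveys
  (and the generator) break this symmetry, but strongly degenerate data can
  produce sparse profiles.
* Elbow selection by second difference is a deterministic proxy for reading
  an inflexion by eye; the WCSS curve and profile are always emitted, and
  `--k` overrides.
* No p-values or multiple-testing control: filtration is by correlation
  magnitude alone, by design.
* Missing values are rejected, not imputed; a pH row in the element table is
  excluded by default (`include_ph=True` to keep it).
* With `cluster_space="pc_scores_2d"` the rotation-invariance equivalence to
  row-space clustering no longer holds; it exists to mirror score-plot
  delimitations.
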