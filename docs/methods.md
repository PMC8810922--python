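# Methods

## The modeling problem

A genome-scale CRISPR knockout screen assigns each (cell line, gene) pair a
gene-effect score (CERES), scaled so the median common essential gene sits
near −1 and nonessential genes near 0. Most genes score near one of those
anchors in every line; a minority are *context specific* — their knockout
phenotype varies across cell lines. `depcompress` asks two questions about
that variation:

1. Can a gene's cross-cell-line phenotype profile be predicted from the other
   measurements made on the same lines (other genes' knockout phenotypes,
   expression, copy number, mutations, lineage)? Which features do the work?
2. Can a small panel of "landmark" genes be measured instead of the whole
   genome, with the rest of the profile inferred — a lossy compression of the
   screening library?

## Per-target models

For a target gene the design matrix concatenates, per cell line: CERES of
every other gene, log2(TPM+1) expression, gene-level copy number, three
mutation-class indicator blocks (damaging; non-damaging hotspot; other
conserving/non-conserving), and one-hot lineage. The target's own CERES
column is excluded; its own expression/copy-number/mutation columns are kept,
carrying the same-gene "dosage" relation.

Cleaning and pruning, applied before modeling:

- cell lines with any missing CERES value are dropped; missing copy number
  loads as 0;
- constant columns are removed; indicator columns supported by ≤ 10 cells are
  removed; expression columns whose gene never reaches 1 TPM in any line are
  removed ("never expressed" is read as max-over-lines — the natural reading
  of a non-expressed gene; mean- or per-line variants would prune more);
- expression and copy-number columns are z-scored with statistics from the
  *training* cells only (leakage hygiene; the training/held-out boundary is
  the 85/15 uniform split).

Targets are the context-specific genes: sample SD (n−1 denominator) > 0.25
CERES units and range (max − min) > 0.6.

The model chain per target, all random forests with 1000 trees, depth 15,
min 5 samples per leaf, ⌈log2 F⌉ candidate features per split (defaults in
`ModelConfig`; desk-scale runs shrink the forest, see *Problem sizes*):

1. **full** — forest on every surviving feature;
2. **iterative selection** — keep the top importance quartile (⌈0.25·F⌉,
   ties broken by column order) and refit, three times;
3. **Boruta confirmation** — shadow-feature scheme: each iteration appends an
   independently permuted copy of every live feature (padded to ≥ 5 shadow
   columns), fits, and scores a *hit* when a feature beats the best shadow.
   Features are confirmed/rejected by a two-sided binomial test (p = 0.5)
   with Bonferroni adjustment over live attributes, α = 0.05, up to 100
   iterations. Features still tentative at the end are kept only if their
   median importance exceeds the median best-shadow importance over the
   iterations they were live **and** they won a majority of shadow
   comparisons. The extra majority requirement is this package's tie-break:
   without it, pure-noise features with chance in-sample correlation were
   kept at ~7%, above the ~5% error the binomial machinery is meant to
   control.
4. **reduced** — forest on the confirmed set; **top-10** — forest on its ten
   most important members (importances from the reduced refit);
5. **univariate** forests (one per top-10 feature), and baselines: ordinary
   linear regression, elastic net (α = 0.1), and a single-pass RF-quartile
   model;
6. **nearest-neighbor null** — a test line receives, gene-by-gene, the CERES
   profile of its nearest training line by Euclidean distance in a 2-D
   expression-space embedding (ties to the smallest cell ID; a line never
   matches itself).

Importance is mean impurity decrease throughout — the default for this
regressor family; permutation importance would roughly double the cost of
the selection loop without changing what the desk-scale tests measure.

## Scoring

- **R²** = 1 − SS_res/SS_tot (can be negative out of sample). Model-filter
  R² is 5-fold cross-validated on the training split; test-set R² is
  reported separately.
- **recall** — Spearman correlation of prediction vs the actual target
  profile, ranked against 1000 null Spearman correlations computed against
  the actual profiles of uniformly drawn non-target genes (with
  replacement; strict inequality). A model that has learned nothing is
  uniform on [0, 1] — verified by a calibration experiment.
- **concordance** — fraction of lines where prediction and truth fall on the
  same side of the −0.6 essentiality cutoff.
- **predictable targets**: recall > 0.95, cross-validated R² > 0.1, and at
  least one top-10 univariate R² > 0.

## Prediction network

Top-10 models pool into a directed graph: feature → target, edge attributes
carrying the data source and importance; lineage features become labeled
nodes; parallel edges collapse keeping the maximum importance. Louvain
communities (resolution 1.0, seeded) are extracted on the undirected
projection. Statistics: mean local clustering coefficient, mean neighbor
count, and degree heterogeneity = √var(k)/mean(k) (the coefficient of
variation used by common network-statistics tools). Stripping CERES-source
edges (and the nodes this isolates) gives the "genomic-only" contrast;
per-node clustering and degree distributions are compared by two-sided
t-tests, with p = 1 by convention when the distributions are identical.
The degree distribution on nodes of degree ≥ 2 is fit to y = a·x^b by
least squares in log–log space (exact on noiseless power-law counts).
The module-regression vignette regresses a core module's mean CERES on two
candidate upstream modules' means (OLS; coefficients, two-sided t-tests,
AIC/BIC per model). The edge-density vignette tests *depletion* of
cross-edges between two node sets against a degree-preserving
double-edge-swap null with the add-one estimator (1 + #{null ≤ obs})/(n+1).

## Lossy compression

Landmark panels are centroids of *tight clusters*: repeatedly subsample 70%
of cells, k-means the gene profiles (k = clusters-still-needed + 5, one
initialization per resample), and accumulate pairwise co-membership over 10
resamples; a tight cluster is the largest maximal gene set with pairwise
co-membership ≥ 0.8 (ties by mean co-membership); extract it, remove its
genes, repeat. The centroid is the member with the highest mean
co-membership (ties by distance to the cluster mean profile, then symbol).
Genes are clustered on per-gene z-scored profiles: on raw profiles the
near-constant essential/nonessential blobs — whose fixed noise vectors give
k-means stable splits under cell resampling — form the largest "tight"
clusters and crowd the informative pathway clusters out of small panels.
Magnitude information is not lost: the downstream forests see raw CERES.
When no multi-gene tight cluster remains, the panel is filled with
singleton clusters chosen by descending profile variance (set
`allow_singletons=False` to get an error reporting the achieved count
instead).

One forest per genome gene is then trained with only the panel's CERES
columns as features (a panel gene's model excludes itself); inference
applies every model to a new line's panel measurements, and panel genes
pass through their measured values exactly. Fidelity is Pearson r over all
(cell, gene) pairs, overall and per essentiality class; "hits" for overlap
counting are the n_top most negative values of score minus the per-gene
training mean (differential requirement, not raw rank — raw CERES rank
would just re-find common essentials). Compression models skip Boruta: the
feature space is already the panel.

## Synthetic data: what it emulates, and what it does not

The generator plants a known data-generating process in DepMap's shape:

- latent pathway factors F ~ N(0, 1) per cell with a per-lineage mean shift
  (SD 0.5), so lineage indicators carry real signal;
- class means −1 / −0.3 / 0 for common essential / selective / nonessential
  (fractions 0.20/0.35/0.45 of 1200 genes by default);
- each selective gene loads on one factor, magnitude 0.6 × U(0.7, 1.3), one
  common sign per factor — co-functional knockouts correlate positively;
  anticorrelation enters only through planted paralog pairs (partner moved
  onto the same factor with opposite sign);
- private mechanisms on disjoint selective genes: synthetic lethality
  (damaging mutation in a partner gene, Bernoulli 0.15, effect −0.8),
  dosage (own log-expression z-score × −0.5), lineage effects (−0.7 for one
  lineage); plus decoy mutations in all three annotation classes, including
  a rare tail that exercises the ≤ 10-support pruning rule, and one lineage
  of exactly 8 cells;
- expression is log-normal around per-gene baselines with lineage shifts;
  a 10% never-expressed fraction stays below 1 TPM everywhere; copy number
  is a decoy channel near 1; the 2-D embedding is the two leading principal
  directions of the standardized expression + copy-number block;
- i.i.d. N(0, 0.15) measurement noise on every CERES entry.

Effect sizes were fixed once at values giving realistic signal-to-noise
(planted selective genes pass the variability filter with SD ≈ 0.4–0.9,
comparable to highly selective DepMap genes). What the generator does *not*
emulate: guide-level noise and copy-number artifacts (scores are consumed
post-correction), correlated omics beyond the planted channels, continuous
essentiality gradients within classes, and any real biological annotation.
Passing tests therefore demonstrate that the machinery recovers a known
architecture at realistic noise — not that real DepMap data has that
architecture.

The negative-control condition ("architecture-free") sets every gene
nonessential with no planted effects. Keeping essentiality class structure
in the control would let per-gene training means alone produce a large
overall correlation, masking what the control is meant to show.

## Problem sizes and numerical choices

Desk-scale runs (tests, `scripts/acceptance.py`, the `analysis/` drivers)
use the default generator (300 cells × 1200 genes, 40 factors) with
100-tree forests and ≤ 50 Boruta iterations; the dominance sweep fits 3
sampled selective targets in each of 10 seed-swept datasets; compression
fidelity is evaluated on a 400-gene uniform subsample (plus the panel);
the saturation sweep uses a 20-factor, 600-gene, 200-cell dataset with
panel sizes {5, 10, 20, 30} and 6 resamples per clustering. These sizes
keep each experiment in single-digit minutes on one CPU while leaving the
tested effects far from their decision thresholds.

Other conventions: splits, forests, shadow permutations, null draws,
subsampling and rewiring all derive from one seed; quartile counts use the
ceiling; importance ties break by column order; k-means ties on duplicate
points follow assignment order; recall uses strict inequality;
`hit_overlap` sorting is stable.

## Known limitations

- Boruta decisions start at iteration 5 and are sequential; the Bonferroni
  adjustment makes them conservative rather than exactly α-level.
- Tight clustering is greedy (largest-first); it does not revisit earlier
  extractions, and panels larger than the true cluster count fill with
  variance-ranked singletons.
- The permutation count in the correlation-vs-variability analysis trades
  p-value resolution for time; the analysis driver uses 50 permutations.
- The nearest-neighbor null depends on the embedding supplied; with the
  generator's expression-PCA embedding it captures lineage structure only.
- `module_regression` assumes module membership is given; it does not search
  for modules.
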