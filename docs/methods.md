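# Methods

This note documents the statistical procedures morphomap implements,
the choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make results reproducible.

## Normalization and profiles

Per-cell features are normalized per plate against the untreated
(negative-control) population: subtract the control median, divide by
the control MAD times 1.4826 (the constant that makes the MAD agree
with the standard deviation under normality).  A feature whose control
MAD is zero on *any* plate carries no robust scale information on that
plate and is excluded from every plate, so profiles stay comparable
across plates.  A mean/sd variant (`robust=False`) exists for the
single-cell clustering step, where plain z-scoring is a defensible
alternative; robust is the default everywhere.

Well profiles are the per-feature median, the per-feature MAD
(`mad_`-prefixed) and the cell count — 2F + 1 components.  The count is
appended as a raw count (so the aggregation output is interpretable)
and converted to a per-plate control-referenced robust z-score by
`zscore_cell_count` before any variance-based step; left raw, its
variance (~10²) would dominate PCA and collapse the reduced space.
When a plate's control counts have zero MAD the plate-wide MAD is the
fallback scale.

Median polish removes additive row/column plate-position trends,
independently per plate and per profile component: alternately subtract
row medians and column medians of the physical well grid until the
largest adjustment in a sweep is ≤ `tol` (default 1e-6).  The default
iteration cap is 500: on even-dimensioned grids the iteration converges
geometrically rather than in finitely many steps, and 100 sweeps (a
natural first guess) routinely stops short.  Missing wells are skipped
via median-over-available; the accumulated row/column effects are
returned on request and reconstruct the input exactly
(residual + row effect + column effect = input).  Polish is applied per
plate rather than jointly across plates; a plate is the physical unit
on which gradients (edge evaporation, dispensing order) act.  One
caveat the pessimistic null (below) exists to quantify: with treatments
at fixed well positions on every plate, whatever positional trend
polish does *not* remove is shared across replicates and inflates
replicate correlations.

## Feature selection

The replicate correlation of a profile component is computed per
unordered pair of replicate plates as the Pearson correlation of the
component's per-treatment values (negative controls excluded), then
averaged over pairs; the mean was chosen over the median because the
number of pairs is small (10 for five replicates) and the mean uses all
of them — a `pair_aggregate="median"` flag switches.  Pairs where
either side has zero variance contribute 0 (no reproducible signal).
Filtering keeps components with replicate correlation ≥ 0.30.

Greedy selection starts from the single component with the highest
replicate correlation (the procedure needs a seed set and the data
itself nominates the most reproducible feature; an explicit
`seed_features` list overrides).  At each step every remaining
candidate is regressed with OLS (intercept included, so residuals are
invariant to affine shifts) on the already-selected features whose
Pearson correlation with it exceeds 0.50 — restricting the regressors
prevents overfitting once many features are selected — and the
candidate whose residual has the largest replicate correlation is
added; selection stops when that maximum drops below 0.30.  Ties break
lexicographically by feature name, making the procedure deterministic
given the input.  PCA runs on mean-centered, unscaled values (the
components already share the robust-z scale) and keeps the smallest
number of leading components reaching 99% cumulative explained
variance, after discarding numerically null directions of
rank-deficient input.

## Hit calling

Profiles are first centered to the per-plate median negative-control
vector, so a treatment without a phenotype scatters about the origin
and its replicates decorrelate, while a consistent phenotype places all
replicates in the same off-origin direction.  Phenotype strength is the
median Pearson correlation over a treatment's replicate pairs.

The null distribution is built from non-replicates.  Two constructions
are provided.  The *pairwise* null pools the correlations of all
profile pairs belonging to different treatments and takes the 95th
percentile — the natural reading of "correlations between
non-replicates", and the cheaper one.  But the test statistic is a
median over ~10 pairwise correlations, which concentrates far more
tightly than a single pair correlation; comparing it against the
pairwise null would be extremely conservative (essentially zero hits
under a global null, not 5%).  The *group-matched* null therefore
samples random groups of R profiles from R distinct treatments — one
per replicate plate, mirroring the replicate structure — and pools the
groups' median pairwise correlations; by construction the statistic of
a null treatment is a draw from this distribution, so the hit rate under
a global null converges to the nominal 5%.  `call_hits` uses the
group-matched null (2000 sampled groups, seeded); `null_threshold`
exposes both via `group_size`.

The pessimistic null restricts the pool to correlations between
negative-control profiles occupying the same well position on different
plates, excluding the outermost ring of edge wells; it preserves any
residual position artifact that replicates (which share well positions)
would also enjoy, and so bounds the optimism of the standard null.

Hits use strict inequality against the threshold; treatments exactly at
the threshold are logged.  Hit profiles are collapsed to the
component-wise replicate mean, and a hit is confirmed only if its
collapsed profile's mean Euclidean distance to the untreated profiles
exceeds the 95th percentile of untreated pairwise distances — a second,
independent notion of phenotype strength that filters treatments whose
replicates agree but sit inside the control scatter (in synthetic runs
these are mostly positional false positives).  `HitCallResult` keeps
both lists: `hits` (statistic above threshold) and `final_hits` (also
passing the distance check).

Secondary comparisons on the same statistic: per-pair correlation of
same-gene construct clones against the 95th percentile of
different-gene pair correlations; a one-sided paired t-test for
engineered-allele vs wild-type strength (degenerate zero-variance
differences return p = 0.5 for zero mean, 0/1 otherwise); per-pathway
mean ± sd of member strengths, with duplicate wild-type clones of a
gene averaged first so each gene counts once.

## Gene map

Collapsed hit profiles are correlated pairwise (constant profiles are a
reported error) and clustered by average linkage on distance 1 − r.
Cutoffs are stated as correlation levels; cutting at level c means
cutting the tree at height 1 − c.

The "highly correlated" threshold for enrichment is the crossing point
of the two estimated densities of same-gene and different-gene pair
correlations, located between the two sample means; thresholding at the
density intersection minimizes the probability of misclassifying one
kind of pair as the other.  Densities use a Gaussian kernel with
Silverman bandwidth — no estimator is canonical here, and Silverman is
the standard parameter-free default.  Enrichment is a one-tailed
(greater) Fisher's exact test of the 2×2 table (correlated yes/no ×
annotated yes/no), computed on one wild-type construct per gene.

The flat cutoff is chosen by stability: for each grid value
c ∈ [0.43, 0.70] (step 0.002) the score is the fraction of treatments
whose cluster — compared as the full member *set*, which is stricter
and order-free — is identical when cutting at c − ε and c + ε with
ε = 0.002.  Scores are smoothed by a centered moving average of width
0.02 on the cutoff axis (11 grid points); the argmax wins, smallest
cutoff on ties.  Per-cluster summaries report the mean within-cluster
correlation, the mean correlation to every other cluster, and the five
outside treatments most negatively correlated with the cluster
(ranked by mean correlation to its members).  Singletons stay in the
partition, flagged, with undefined within-correlation.

## Subpopulations

For a gene cluster, normalized cells of the cluster's treatments and
the negative controls are pooled, restricted to the selected (pre-PCA)
feature set, and partitioned with k-means (k = 20 by default, Lloyd
iterations capped at 5000).  Initialization is k-means++ with an
explicit seed and 5 restarts (best inertia wins) — a single restart
occasionally lands in an unbalanced local optimum that merges two
genuine subpopulations, which distorts the proportion statistics
downstream.  After fitting, every cell is re-assigned to its nearest
center; that invariant, not the k-means labels, defines membership.

Proportions are computed per gene with cells pooled across replicates
(one proportion vector per gene) and for the pooled control.  For each
subpopulation the change d_g = p_g − p_control over the cluster's genes
gives the inverse coefficient of variation |mean d| / sd d (sd with
ddof = 1); ICV > 1 declares a consistent enrichment (mean > 0) or
depletion (mean < 0).  Zero spread with nonzero mean is reported as
consistent with infinite ICV and a warning.  Subpopulations below 0.5%
abundance in both the cluster average and the control are omitted from
reporting — "very small" needs a number, and 0.5% of cells is below
what exemplar images could illustrate anyway.  Exemplars are the n
member cells nearest the center, ascending; the DNA-content histogram
is a plain binned count of the configured integrated-intensity feature
over the cluster's cells.

## Interpretation summaries

The Feature Grid aggregates the collapsed, control-referenced profile
values of a cluster into median z-scores per (measurement type,
channel): the median is taken over the pool of member features ×
cluster treatments.  Channel-free measurement types (shape, neighbor
context) form their own column; combinations with no features are
masked, never zero-filled, and a feature measuring two channels
(cross-channel correlations) contributes to both channels' columns.
Median, not mean, aggregation across cluster members keeps single
outlier treatments from repainting the grid.

The Feature Map takes the top-k features by |median z| (ties broken by
name), computes their correlation matrix across *all* treatments'
collapsed profiles, and embeds distance 1 − |r| with classical
(Torgerson) metric MDS — deterministic, no tuning, axis signs fixed by
the largest-magnitude coordinate.  Each feature carries the sign of its
median z (enriched vs depleted).

## Expression targets

Per replicate column of a gene's landmark expression matrix
(control-normalized), the top 50 and bottom 50 landmarks are listed,
rank ties at the boundary broken by landmark identifier.  A landmark is
an up-/down-target when it appears in the respective list in at least
⌈p · R⌉ replicates (never fewer than one, so p = 0 degenerates to the
union over replicates and p = 1 to the intersection).  Within one
replicate the two lists cannot overlap; a landmark qualifying in both
directions across replicates (only possible for inconsistent signatures
at small p) is kept in both sets with a warning rather than silently
dropped.  Common targets of two genes are the direction-respecting
intersection (up∩up, down∩down).  The construct-score summarization
over cell-line/time-point combinations is the mean of the 4 largest
scores (all of them if fewer).

## Synthetic data

The generator emulates the screen's design: five replicate plates with
every treatment at the same well position on each plate (the real
constraint that motivates the pessimistic null); negative-control wells
spread across the plate by even striding, so they cover interior and
edge rows/columns; per-cell features drawn from a mixture of isotropic
Gaussian subpopulations (diagonal covariance — the simplest structure
that still exercises k-means recovery); treatment effects as
feature-mean shifts along per-group unit directions — orthonormalized
by default, so planted groups are geometrically distinct phenotypes
rather than occasionally near-collinear random draws — plus
per-treatment within-group direction noise, and as
subpopulation-proportion shifts (clipped and renormalized to a
simplex); additive per-feature row/column plate
offsets, by default identical across replicate plates because physical
position effects recur; negative-binomial cell counts (Poisson
under-disperses real well counts); and constant features that exercise
the MAD = 0 exclusion.  Matched annotation sets mark within-group pairs
as interacting/co-pathway with probability 1 − noise and between-group
pairs with probability noise; the landmark-expression generator gives
group mates a shared planted up/down target program.

Default scale fills a 96-well plate (76 treatments + 20 controls,
5 plates, 60 features); tests and benchmarks use smaller but equally
dense plates.  Dense plating matters: median polish over a mostly
empty well grid computes row medians from a handful of wells and
destroys signal.

What the generator does *not* emulate — and what passing tests
therefore do not establish about real data: correlated feature blocks
within cells (features are independent given the subpopulation), heavy
tails and technical outliers, segmentation errors, intensity-dependent
noise, batch effects beyond additive row/column position terms, and any
optical or staining physics.  Recovery rates on this synthetic family
are upper bounds for real screens, not predictions.

## Benchmarks (`morphomap.experiments`)

Fixed study conditions, each seeded end to end:

* **Null calibration** — 200 treatments × 5 replicates, no effects,
  16×15 plate, 30 features, ~50 cells/well; reports the hit rate, whose
  target is the nominal 5%.
* **Effect power** — 18 treatments (20% null) on a 4×6 plate, each
  effect along its own direction; the planted magnitude is *derived*,
  not hand-set: a matched null pilot measures the per-feature replicate
  scatter of polished profiles and the raw control MAD, and the effect
  is scaled so the per-feature normalized shift equals 3× that scatter.
  Power is the fraction of effect treatments among statistic-based hits
  over 20 repeats.
* **Clustering recovery** — 4 groups × 5 treatments, strong effects
  (magnitude 4, an order of magnitude above profile noise, within-group
  direction noise 0.10); adjusted Rand index of the stability-cut
  partition against the planted groups.
* **Subpopulation consistency** — 2 groups × 8 genes + 64 control wells
  on an 8×10 plate, 4 subpopulations, a +5-percentage-point planted
  shift (≈3.6× the across-gene sd induced by multinomial counting at
  ~1000 cells/gene).  Positive rate: repeats in which the planted shift
  is flagged consistent, in the right direction, on the fitted
  subpopulation matching the planted component (matched by each fitted
  subpopulation's majority planted component).  Negative rate: repeats
  in which a random 32/32 split of the control well positions flags
  nothing.  The split size matters: the null ICV of an n-gene split
  concentrates around sd(mean Δp)/sd(Δp) ≈ √(2/n) (the control half's
  own sampling error contributes a term equal to the across-gene one),
  so n = 32 pushes the false-flag probability per subpopulation to
  ~0.05%, making a clean 20-repeat run the overwhelmingly likely
  outcome rather than a coin toss.

`scripts/acceptance.py` runs these plus the Fisher tests on the printed
contingency tables and writes the numbers as JSON.

## Numerical conventions

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipeline stages derive their seeds from
  the global seed by CRC-hashing the stage name (kept below 2³¹).
* Pearson correlations are clipped to [−1, 1]; zero-variance vectors
  are an error where correlation is the object of interest
  (profile correlation matrix) and contribute 0 where a missing value
  must not propagate (replicate correlations of features).
* Percentiles use numpy's default (linear interpolation).
* Ties: lexicographic feature names in selection; smallest cutoff in
  the stability argmax; landmark identifier at rank boundaries.

## Known limitations

* The group-matched null samples 2000 groups; the threshold carries
  Monte Carlo error of a few thousandths in correlation units.
* Median polish assumes additive position effects; multiplicative or
  interaction-structured artifacts are out of model.
* The distance check's power depends on the number of control wells;
  with very few controls its 95th-percentile reference is noisy.
* With few treatments on small plates, strong effects leak into the
  row/column medians that polish subtracts, inducing correlated
  pseudo-signal at null wells; the distance check catches most of it,
  and the pessimistic null quantifies what remains.
* `fit_subpopulations` recomputes nearest-center assignments after
  Lloyd terminates, so assignments are exact even when the iteration
  cap (not convergence) ended the fit.
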