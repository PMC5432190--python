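# Methods

This note records the model, the numerical and design choices behind the
implementation, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Model

A cancer evolutionary tree is a rooted tree whose root is the normal cell,
whose first node is the founder clone, and whose edge lengths count the
SSNVs acquired by each clone. Cohorts of such trees are heterogeneous in
four ways that block naive comparison: different topologies, different node
counts, no node correspondence across patients, and sequencing-depth bias in
absolute SSNV counts. Registration addresses all four:

* **Binarization.** Observed trees may multifurcate; the reference is
  strictly binary. At each node the children are put in a canonical order
  (deepest subtree first; ties by longer connecting edge, then larger
  subtree total length, then canonical-form string, then input position —
  the last two keys only make the order total). The first child keeps its
  edge; remaining children hang off a chain of zero-length "spine" edges.
  Total length is conserved exactly and no terminal depth decreases. The
  spine construction is this package's choice: any length-conserving rule
  that yields a binary tree works, and the choice is recorded on the tree
  (`spine_of`) so downstream consumers can ignore the artifacts.
* **Reference tree.** The complete bifurcated tree of depth
  D = d_max(X), the maximum terminal depth over the (binarized) cohort. Its
  m = 2(2^D − 1) edges are numbered in level order: edges 1 and 2 leave the
  root, and edge k has children 2k+1, 2k+2. Depths are computed after
  binarization so the reference is always deep enough for the mapped trees.
* **Mapping.** The trunk occupies edge 1 (so the root's second slot is
  always degenerate); recursively, a node's canonically first child takes
  the lower-index child slot. Deepest-first with the length tie-break means
  two trees differing only in sibling order in their input files register
  identically. Which root slot the trunk takes is a global convention;
  distances are invariant to any convention applied uniformly.
* **Normalization.** Each mapped length is divided by the tree's SSNV
  total, removing depth-of-sequencing bias; each registered vector z_i sums
  to 1, and rescaling all of a tree's edge lengths by any c > 0 leaves z_i
  unchanged.

Registered trees share one topology (the reference), hence occupy a single
orthant of Billera–Holmes–Vogtmann tree space, which is Euclidean. The
dissimilarity is the squared form s(x_i, x_j) = (z_i − z_j)′(z_i − z_j); the
pipeline's working distance is its square root. This resolves an internal
tension in the method's algebra: the MDS construction squares the distance
matrix element-wise before double-centering, which is only the textbook
Gram construction if the matrix holds Euclidean distances, not squared
ones. Ward clustering likewise operates on the Euclidean distances
(scipy's `ward`, i.e. the ward.D2 squared-update variant), which is the
geometry Ward's objective presumes.

Summary statistics: tree mean μ = (1/n) Σ z_i (an average edge profile that
can be rendered on the reference) and tree variance
σ² = (1/n) Σ (z_i − μ)′(z_i − μ). Note the population 1/n form; for two
points at distance d this gives d²/4.

## Cluster-number selection

The gap statistic compares log W_k (within-cluster sum of squared
deviations from centroids, summed over clusters) against its mean under a
null reference in which each coordinate is drawn uniformly over its
observed range, with `n_boot = 100` reference datasets by default and the
same Ward procedure on each. K is the smallest k with
gap(k) ≥ gap(k+1) − s_{k+1} (one-standard-error rule), scanning
k = 1 … k_max, default k_max = min(n − 1, 10). Cohorts of exactly
duplicated vectors make log W collapse and the criterion degenerate; the
all-identical case returns K = 1 with a warning, and for forced-K use the
`n_clusters` argument bypasses selection entirely. Seeds are explicit
everywhere randomness occurs.

## Interpretation tools

**Classical MDS.** B = −½ H S∘² H with H = I − (1/n)11′ is symmetrized,
eigendecomposed, eigenvalues sorted descending; eigenvalues within
1e−12·λ_max of zero (or negative — rounding noise, since registered
matrices are exactly Euclidean) are clamped to zero and their axes dropped,
zero-padding with a warning if fewer positive axes exist than requested.
Axis signs are fixed deterministically (largest-magnitude loading
positive). The default 2-D embedding is for visualization; `goodness`
reports the positive-eigenvalue mass captured.

**Sub-clonal diversity curve.** For a tree with normalized lengths, clone
birth is placed at the cumulative root distance of its node — an edge must
fully accumulate before the clone exists. y(x) = 1 + #{non-root nodes at
root distance ≤ x}; y below the trunk fraction is 1 (normal cell only), the
founder appears exactly at the trunk fraction, and y(1) = 1 + number of
sub-clonal nodes. Ties merge into one jump of the tied multiplicity, and
queries tolerate 1e−9 of floating noise so evaluating exactly at a jump is
safe. Zero-length spine edges inserted by binarization are encoding
artifacts and are **not** counted as clones; when a curve is computed from
a registered vector rather than a tree, nodes are inferred from the
non-zero edges (a genuinely zero-length original edge would be invisible
there — use the tree form if that matters). The per-cluster summary reports
each tree's trunk fraction (x of the 1→2 jump) and the cluster median.

## Synthetic cohorts

The generator reproduces the benchmark *designs* — class structure, cohort
sizes, and the two spread dials — not any particular published dataset.
Its constants are this package's own reconstruction and live in
`phyc/simulate.py`:

* **Archetypes** (frozen): monoclonal MC (trunk only, 2 nodes), polyclonal
  low/middle/high PL/PM/PH (4/6/10 nodes over 2/3/4 levels), mutator
  phenotype MT (depth-5 caterpillar).
* **Dispersion index** (topology spread): each tree receives a Poisson
  number of random edits with mean 0.25·(index − 1) — index 1 is the exact
  archetype, the strongest-separation setting. Edits choose uniformly among
  inserting a unit leaf under a random non-root node, deleting a deletable
  leaf (≥ 2 nodes kept, trunk never orphaned), and regrafting a leaf.
* **Variance index** (length spread): the trunk's share of SSNVs is
  Beta-distributed around the class center (trunk-accumulation 0.8,
  balanced 0.5, branch-accumulation 0.2) with concentration
  100 / 4^(index − 1); the remaining share spreads over branch edges by a
  symmetric Dirichlet(3). Integer SSNV counts conserve each tree's total
  (drawn uniformly from 50–200) exactly via largest-remainder rounding.
* **Designs.** I: topology classes (MC, PL, PH, MT by default), all edge
  lengths set to 1. II: one topology (PM) × three accumulation classes.
  III: {PL, PM, PH} × {TR, BL, BR}, nine classes. Ten trees per class by
  default; everything is reproducible from the config seed.

What the generator does **not** emulate: tree-reconstruction error (trees
are sampled directly, not inferred from noisy VAF matrices), unequal class
sizes, per-cohort depth heterogeneity beyond what the edits produce, and
any correlation between topology and total mutation burden. Passing
recovery tests therefore demonstrates that the registration geometry
separates the intended tree classes — not that the full pipeline is robust
to reconstruction noise in real cohorts.

At the strongest-separation setting the nine-class design is deliberately
hard in one specific way: the three trunk-accumulation classes put ~80% of
mass on the same reference edge, so their registered vectors are close
regardless of topology and the clustering tends to merge them, capping NMI
around 0.85–0.9 and the Rand index around 0.92 even when everything else is
recovered — the method weighs edge-length contrasts more heavily than
topology contrasts when the length contrast is extreme. The acceptance
script measures exactly this plateau (20 replicates of 90 trees; a few
seconds per replicate on one CPU).

## Evaluation indices

Purity (majority-class fraction per cluster, averaged), NMI (mutual
information over the arithmetic mean of entropies; a √-normalized variant
is available via `normalization="sqrt"`), and the Rand index (pairwise
agreement fraction). NMI's 0/0 case (both partitions trivial) is defined as
1; a single-cluster prediction against a multi-class truth scores 0. Purity
is intentionally not symmetric and rewards over-segmentation (all
singletons score 1) — it is reported alongside the two symmetric indices,
never alone.

## Known limitations

* Registration depends on the cohort through d_max: adding a deeper tree
  re-embeds everyone in a larger space, so distances are comparable only
  within one registered set. Combine cohorts before registering.
* Trees deeper than ~12 levels produce reference spaces of 2(2^D − 1)
  dimensions; the method targets clonal trees of modest depth (2–20 nodes).
* The canonical order's two leading keys (depth, then edge length) follow
  the method's mapping rule; the remaining tie-breaks are arbitrary
  conventions and can place near-tied sub-trees in different slots, making
  near-identical trees register slightly apart.
* The gap statistic inherits its known conservatism and its degeneracy on
  duplicated points; forced-K mode exists for cohorts where K is known.
* No support for unrooted trees, and no attempt to match SSNV identities
  across patients.
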