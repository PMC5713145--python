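# Methods

## Problem and model

Multi-crystal (serial) macromolecular crystallography produces many partial
datasets — small rotation wedges, here of the order of a few percent
completeness each — that must be merged into one complete dataset. Crystals
are not perfectly isomorphous, so the central decision is *which* wedges to
merge. `isomerge` treats this as hierarchical cluster analysis under a
non-isomorphism metric and automates the cut-height choice.

### Distance definitions

The default metric converts the Pearson correlation of common intensities
into a distance:

    d(a,b) = sqrt(1 - cc(a,b)^2)

* Before pairing, each wedge is collapsed to one intensity per unique
  reflection by the inverse-variance weighted mean, so cc does not depend on
  per-wedge multiplicity. Pairing is over asymmetric-unit keys; Friedel
  mates are merged for this purpose.
* The correlation is the plain (unweighted) Pearson coefficient of
  intensities, not amplitudes.
* A pair with fewer than `n_min` common reflections (default 3, tunable) or
  with zero intensity variance has no defined correlation and is assigned
  d = 1. Very small overlaps make cc estimates so noisy that treating them
  as "unknown = maximally distant" is safer than trusting them; the default
  of 3 is deliberately permissive because average linkage later averages
  over many pairs.
* cc ≤ 0 also maps to d = 1 rather than sqrt(1 - cc²). The algebraic form
  is symmetric in the sign of cc, but an anticorrelated pair is maximally
  non-isomorphous, and 1 is the same sentinel used for incompatible cells.
* Pairs whose unit cells differ by more than 1% in any of the six
  parameters are assigned d = 1 without computing cc. The relative
  difference is taken against the pair mean (symmetric in the two cells);
  angles are included alongside lengths so that monoclinic drift is caught.
  This gate flags outlier crystals cheaply.

The alternative cell metric is d(a,b) = max(|Δa|, |Δb|, |Δc|) in Å — the
maximal variation of a unit-cell length. It is always defined but is
unreliable for very thin wedges, where cell parameters are poorly
determined; the cc metric is therefore the default.

### Clustering and cutting

Average linkage (UPGMA): the distance between clusters X and Y is the mean
of the N_X · N_Y pairwise dataset distances. The implementation delegates to
`scipy.cluster.hierarchy.linkage(method="average")`; tests verify its merge
heights against an O(n³) brute-force reference on random matrices. Leaves
are numbered 0..N−1 in manifest order, internal nodes N, N+1, … in merge
order, and the linkage table is written in that convention.

Cutting at height t keeps all merges with height ≤ t and returns either the
full partition (`mode=all`) or only the largest cluster (`mode=largest`,
the default; size ties resolve to the cluster containing the smallest leaf
index, so reruns are byte-identical).

### Threshold estimators

* **Minimal for completeness.** Scan the merge heights in ascending order
  (cluster composition only changes there, so no grid is needed); at each
  height pool the unique reflections of the largest cluster and compute
  completeness against the theoretically observable unique set; return the
  smallest height reaching the target (default 98%, tunable). If the target
  is never reached the maximal height is returned with a warning. The
  resolution limit for the completeness calculation defaults to the best
  resolution observed across the input datasets.
* **Growth heuristic.** Return the merge height at which the largest
  cluster's size increases most over the previous height (earliest height
  on ties, evaluated as a discrete difference between consecutive distinct
  heights; a smoothed derivative would be the alternative reading, but the
  discrete form is exact on the only points where anything changes). The
  final merge is excluded as a candidate whenever any other merge exists:
  the root join always absorbs every remaining dataset, so a threshold
  there selects everything and defines no clustering.

Because cluster composition is evaluated for the *largest* cluster, the
completeness-versus-threshold curve is non-decreasing whenever the largest
cluster grows by absorbing its predecessor; at small sizes the identity of
the largest cluster can switch between branches, which may lower pooled
completeness by a fraction of a percent. The minimal-threshold estimator is
unaffected (it looks for the first crossing), and the tests assert
monotonicity along nested growth.

The conversion between a cut height and the expected average pairwise
correlation inside the selected cluster is the closed form cc = sqrt(1−d²):
d = 0.40 ↔ cc ≈ 92%, d = 0.64 ↔ 77%, d = 0.32 ↔ ≈ 95%.

### Symmetry handling

Reciprocal-space equivalence is h′ = h·R over the rotation parts of the
space-group operators; the canonical asymmetric-unit representative is the
lexicographically greatest index of the orbit (including the
Friedel-inverted orbit when Friedel's law is assumed true, or for centric
reflections). This convention is library-independent and trivially
testable. With anomalous merging the key records which Bijvoet branch an
observation belongs to relative to the canonical representative.

Operator tables for P1, P2₁2₁2₁, P4₁2₁2, P4₂2₁2 and P4₃2₁2 are embedded
explicitly (these cover the tetragonal/orthorhombic cases in the tests);
any other group is constructed from its IT number via `gemmi`, and the
embedded tables are cross-checked against `gemmi` in the test suite.

Systematic absences (h·R = h with non-integral h·t for some operator) are
screened when counting theoretically observable unique reflections.
Observed reflections indexed at absent positions are kept as data —
rejecting them is the integration software's business.

### Merging and statistics

Merged intensity per unique reflection: inverse-variance weighted mean,
I = Σ(Iᵢ/σᵢ²)/Σ(1/σᵢ²), σ = sqrt(1/Σ(1/σᵢ²)). No inter-dataset scaling is
applied by default — the synthetic generator produces data on a common
scale, and scaling/correction of real data is normally done upstream. An
opt-in per-dataset multiplicative scale (median intensity ratio against the
running merged reference) is provided for data that need it.

Statistics (overall and in `n_shells` resolution shells of equal volume in
1/d³ between the observed d_max and d_min):

* completeness — unique reflections present ÷ theoretically observable
  (Bijvoet mates counted separately when anomalous);
* multiplicity — observations ÷ unique present;
* Rmerge = Σ_h Σ_i |Iᵢ − ⟨I⟩| / Σ_h Σ_i Iᵢ with the unweighted group mean;
  Rmeas multiplies each group's numerator by sqrt(n/(n−1)), Rpim by
  sqrt(1/(n−1)). Groups observed once are excluded from both numerator and
  denominator; if no group is multiply observed the R-factors are reported
  as absent, not 0.
* CC½ — observations of each multiply-observed group are randomly split
  into two halves (the odd observation alternates between halves across
  groups) and the per-group half-means are correlated. The split is
  governed by a recorded seed, so reruns are identical. The random-split
  construction was chosen over the σ-τ analytic form because it is directly
  testable against the closed-form expectation var_signal/(var_signal +
  var_noise) on simulated doublets.
* ⟨I/σ(I)⟩ — mean of merged I/σ over unique reflections.
* sigAno — mean over keys with both Friedel mates of
  |I⁺ − I⁻| / sqrt(σ⁺² + σ⁻²), computed on intensities (no
  French–Wilson conversion to amplitudes is in scope; an
  amplitude-based definition would differ). Under a null anomalous
  signal this statistic concentrates at the half-normal mean
  sqrt(2/π) ≈ 0.798, which the tests verify.

Singleton groups count toward completeness and multiplicity but not toward
R-factors or CC½ (standard convention).

## Synthetic data generator

The generator emulates the *intensity-overlap structure* of a wedge
experiment, not its geometry: hierarchical clustering consumes only which
reflections two wedges share and how correlated their intensities are, so
wedges are modelled as contiguous blocks of the sorted unique-reflection
list (70% of the expected coverage) plus uniform random scatter (the
remainder, with the scatter rate chosen so expected coverage equals
`wedge_fraction` exactly). Ray-traced rotation geometry, radiation damage
and detector effects are deliberately out of scope — conclusions from these
tests are about the clustering/merging mathematics, not about integration
artefacts in real data.

* **Latent intensities** are log-normal (shape σ_log = 1, mean 1000):
  positive and heavy-tailed, loosely mimicking Wilson statistics without
  claiming physical realism.
* **Between-class correlation**: class log-intensities mix a shared and a
  private standard-normal component; the mixing weight w solves
  (e^(s²w) − 1)/(e^(s²) − 1) = between_cc, the exact Pearson correlation of
  correlated log-normals, so the target is met analytically rather than by
  tuning.
* **Within-class correlation**: each dataset multiplies the class truth by
  (1 + η), η ~ N(0, τ) i.i.d. per reflection, with τ solved from
  Var(I)/(Var(I) + τ²E[I²]) = within_cc.
* **Noise**: Gaussian with σ = noise_level × I; the σ column records the
  true noise level. **Cell jitter**: one relative perturbation of the cell
  lengths per class. **Anomalous signal**: per-reflection relative Bijvoet
  difference δ ~ N(0, anomalous_signal), applied as I± = I(1 ± δ/2); both
  Friedel mates of every sampled reflection are written.

Default configuration (the conditions the package is demonstrated under):
tetragonal cell 58.07 × 58.07 × 150.56 Å in P4₁2₁2 to 1.8 Å, 184 wedges in
two isomorphism classes (138 + 46), within_cc = 0.95, between_cc = 0.30,
wedge_fraction = 0.049 (≈ 2500 observations per wedge counting both
mates), noise_level = 0.05, cell_jitter = 0.002. These are the scale of a
realistic serial data collection: ~184 usable 2° wedges of ~4.9%
completeness each, with a dominant isomorphous cluster containing roughly
two-thirds of the crystals.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; outputs are byte-identical across reruns.

## Numerical and design notes

* Unique-reflection enumeration bounds each index by cell-length/d_min + 2
  and then filters by exact d; results are cached per (cell, group, d_min,
  anomalous). d-spacings use the general reciprocal-metric-tensor form and
  are cross-checked against closed forms and `gemmi`.
* Miller indices are packed into sortable 64-bit integers (20 bits per
  index plus a Bijvoet bit), so set operations on reflection keys are
  vectorised `numpy` intersections.
* Merge heights from average linkage on a proper distance matrix are
  monotone; the tree validator requires exactly n−1 merges and consistent
  sizes. Cuts use an inclusive comparison (height ≤ t + 1e-12).
* Degenerate inputs: (0,0,0) indices are rejected; σ ≤ 0 observations are
  dropped at read time and counted (XDS flags misfits with negative σ);
  empty datasets, duplicate manifest ids/paths, mixed space groups under
  the cc metric, and non-finite distances are hard errors.
* Test problem sizes: the two-class recovery experiment uses 40 + 40
  wedges of 5% completeness at the full 1.8 Å study scale, repeated over
  100 seeds; the completeness-surface check uses the full 184-wedge default
  configuration. These sizes keep each experiment to a couple of minutes
  while leaving the per-pair overlap (~60 common reflections) large enough
  for stable correlation estimates.

## Known limitations

* No inter-dataset scaling or error-model refinement; real unmerged data
  with strong scale variation should be scaled upstream or with the opt-in
  median-ratio flag.
* No outlier rejection of individual observations.
* sigAno is intensity-based; published amplitude-based values are not
  directly comparable.
* Rhombohedral/hexagonal settings and non-standard settings rely on
  `gemmi`'s operator tables and are untested beyond operator validity;
  twinning is out of scope.
* The growth heuristic assumes the dendrogram has a dominant cluster; on
  data with many equally sized classes the completeness-based estimator is
  the more meaningful choice.
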