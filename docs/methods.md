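# Methods

This note records the models implemented, the parameters that matter,
and the design choices made where more than one defensible option
existed.  Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Distance and diversity metrics

**Weighted UniFrac.** For two communities A, B on a rooted phylogeny
with branch lengths, the raw distance is `Σ_b ℓ(b)·|p_A(b) − p_B(b)|`,
where `p_X(b)` is the fraction of community X's reads on leaves
descending through branch `b`.  The normalised variant divides by
`Σ_j depth(j)·(p_A(j) + p_B(j))` over leaves `j` (root-to-leaf path
length), bounding the value in [0, 1].  The **normalised form is the
pipeline default**: the classifier bins distances in widths of 0.1, and
a [0, 1] range means at most ten bins tile the space.  The raw form is
kept behind `normalized=False`.  The matrix routine computes a
samples × branches proportion matrix once and takes branch-length
weighted L1 distances between rows; tests verify it against a per-pair
brute-force implementation that enumerates descendant leaf sets, and
against scikit-bio's implementation.

**Chao1** uses the bias-corrected form
`S_obs + F₁(F₁−1)/(2(F₂+1))`, defined even when no doubletons exist;
the classic `F₁²/(2F₂)` form is available by flag and raises when
`F₂ = 0`.  **Faith PD** sums the branch lengths of the minimal subtree
connecting the observed leaves *including the root-connecting
branches*; PD values would differ by the stem length under the other
convention, so this is stated explicitly.  **Rarefaction** is a single
multivariate-hypergeometric draw per seed; the analytic expected
richness `Σ_i [1 − C(N−N_i, n)/C(N, n)]` is provided as its oracle.

## Ordination and pseudo-replication

PCoA applies Gower double-centering to `−½ D∘²` and eigendecomposes;
coordinates are eigenvectors scaled by `√λ` on the positive-eigenvalue
axes.  UniFrac matrices need not be Euclidean-embeddable: **negative
eigenvalues are dropped** and their absolute-value share of the total
eigenvalue mass is recorded on the result and logged (no
Lingoes/Cailliez correction — the simplest auditable choice).
Multiple biopsies from one patient at one timepoint are collapsed to
their arithmetic-mean centroid **in the full positive-eigenvalue
space**, not the 2–3 axes one would plot.  Between-centroid values are
therefore ordination-space Euclidean distances; the field often calls
these "UniFrac distances", which is loose — the discrepancy is
deliberate and documented here.

## Group inference

The permutation t-test recomputes the Welch statistic under random
relabelings of the pooled values; `p = (1 + #extreme)/(reps + 1)` so
zero is never reported.  When the number of distinct label assignments
`C(n, n_x)` does not exceed the replicate budget the test **enumerates
them exhaustively** and the p-value is exact (the observed assignment
counts itself).  The Welch form of the statistic is used throughout for
consistency with the per-taxon tests; under a permutation null the
choice of t-variant is second order.  Distance pools follow the
per-individual averaging rule: when an individual contributes several
pairwise distances to one comparison (e.g. inflamed vs
healthy-appearing biopsies), their mean enters the pool as a single
value.  Per-taxon comparisons average relative abundances per patient
per timepoint before a Welch test across patients; raw p-values are the
primary output with Benjamini–Hochberg q-values alongside.

## The binned likelihood classifier

Training pools are the UniFrac distances observed under each outcome.
Bins are half-open `[k·w, (k+1)·w)` with `w = 0.1` by default and a
ceiling at the smallest multiple of `w` covering the training maximum;
test distances beyond the ceiling fall into the last bin.  Each class
is first normalised to a frequency distribution over bins (**equal
class priors**), then `P(rec|bin) = f_rec/(f_rec + f_rem)`; for every
defined bin `P(rec) + P(rem) = 1`, and swapping the classes maps
`P → 1 − P` exactly.  Equal-prior normalisation was chosen so that
unequal class pool sizes cannot masquerade as signal; raw-count pooling
is retained behind `class_normalized=False`.  Bins empty in both
classes are *undefined* and contribute the uninformative prior 0.5 at
prediction time (nearest-defined-bin borrowing was rejected as harder
to audit).  A patient's probability of recurrence is the arithmetic
mean over their distances; a tie at exactly 0.5 is flagged
*indeterminate*, never silently broken.  Three distance pools are
supported — Crohn's surgical biopsies vs surgical controls, vs all
controls, and within-patient through-time — each yielding its own
model.  Leave-one-patient-out validation refits the model on the other
patients' aggregated distances for every fold; reported summary is
accuracy plus mean ± s.d. of the winning-class probabilities.

Robustness exercises: `single_biopsy_resampling` draws one biopsy per
Crohn's patient and a *distinct* random control per comparison, Welch
tests remission vs recurrence distances, and reports the significant
fraction over (default) 10,000 repetitions; `combination_tests`
enumerates every one-biopsy-per-patient selection (count = product of
per-patient biopsy counts) against the control centroid in ordination
space.

## Sequencing-error simulation

The error model is **substitution-only** ("mismatches"): each base is
independently replaced with probability ε by one of the other three
bases uniformly.  All reads share one length, so identity is
`1 − hamming/L` over the full read length — the strictest, simplest
convention (no end-gap forgiveness, no indels).  Clustering is greedy
and abundance-ordered in the uclust style of the QIIME era: uniques are
processed in decreasing abundance (ties lexicographic) and join the
first centroid, in creation order, within the mismatch radius, else
open a new centroid.  The implementation batches this by
centroid-creation event, which is provably equivalent to the per-read
greedy rule and is verified against a brute-force re-implementation in
tests.  Retention (`≥ 2 samples` and `≥ 10` combined copies, both
inclusive) and contaminant filters (removed iff a verbatim substring of
a contaminant reference *and* absent from every allowed reference)
match the described preprocessing.  The inflation experiment runs
inject → dereplicate → cluster over an (ε, depth) grid at desk scale —
default 10⁵ reads of 100 bp against 20 reference sequences — rather
than the hundreds of millions of reads of a production run; the
qualitative result (error and depth inflate OTU counts far beyond the
reference richness) is scale-independent and is what the tests assert.

## Synthetic cohort generator

The generator emulates a post-operative resection cohort: 3 remission + 3 recurrence
Crohn's patients biopsied at surgery (t1) and post-operative
colonoscopy (t2), 8 controls (half surgical, half colonoscopic) at one
timepoint, 3 biopsies per patient-timepoint, 64 taxa on a random
bifurcating tree (exponential branch lengths, mean 0.1).  Each patient
has a latent log-abundance vector = baseline + group offset + patient
noise; biopsies are multinomial draws (depth 2000) from the softmax of
that vector plus biopsy-level noise (σ 0.1).  Defaults:

| parameter | value | role |
|---|---|---|
| `sigma_control` | 0.3 | control patient dispersion (tight cluster) |
| `sigma_crohns` | 0.6 | Crohn's dispersion (> control) |
| `delta` | 20 | recurrence offset along a fixed random direction |
| `tau_remission` / `tau_recurrence` | 0.3 / 1.5 | t1→t2 drift s.d. |

`delta` is a vector norm over 64 taxa, i.e. per-taxon log-offsets
around 2.5 — severe dysbiosis in which the recurrence community's
dominant taxa are largely replaced.  This magnitude matters: the
classifier bins normalised UniFrac distances in widths of 0.1, so the
planted separation must span several bins to be learnable at all, which
small log-scale nudges (invisible after softmax in 64 dimensions) do
not produce.  The offset direction is fixed per simulation; a
`per_patient_direction` flag randomises it per patient to emulate
"every unhappy gut is unhappy in its own way".  With these defaults the
6-patient leave-one-out recovery, the distance-direction and the
stability-direction checks all pass with margin (measured by the
acceptance tests themselves).

What the generator does *not* emulate: 16S sequence evolution along the
tree, chimeras, batch/run effects, variable sequencing depth,
compositional zero-inflation beyond multinomial sampling, or more than
two timepoints.  Passing tests therefore show that the *analysis
machinery* is correct and recovers planted structure at this cohort
scale — not that real mucosal biopsies carry this much signal.

## Numerical choices and degenerate inputs

Bin assignment uses `floor(d/w + 1e-12)` so values at a bin edge land
in the upper bin deterministically.  Permutation extremeness uses a
`1e-12` tolerance on `|t|` to absorb float noise in enumerated splits.
PCoA treats eigenvalues below `1e-10` of the spectral radius as zero;
an all-zero distance matrix yields a single zero axis.  Zero-total
samples, taxa missing from the tree, asymmetric matrices, metadata
vocabulary violations and Rutgeerts scores outside 0–4 are errors, not
warnings.  A cohort where a leave-one-out fold would leave an empty
outcome class raises with the offending fold named.

## Pipeline and reproducibility

`run_pipeline` executes stages in dependency order, persists every
intermediate as TSV, and writes a JSON manifest (config snapshot, seed,
input digests, package version, timestamp).  One global seed fans out
to per-stage seeds by a fixed derivation (`SeedSequence` keyed on the
stage name's CRC), so any stage can be reproduced in isolation; data
outputs are byte-identical across reruns.  A failed run leaves a
`FAILED` marker in the output directory.

## Known limitations

* Distances fed to the classifier and the centroid machinery are
  sample-level UniFrac or ordination-space Euclidean values; the two
  coincide only when the distance matrix is Euclidean-embeddable.
* The greedy clustering is order-dependent by design (it models the
  behaviour of the era's tools), so OTU counts are a property of the
  rule, not a global optimum.
* The permutation test conditions on the observed values; with very
  small pools its p-value granularity is coarse (minimum `1/C(n,n_x)`).
* Welch tests on 3-vs-3 skewed distance pools (the single-biopsy
  exercises) are conservative; the null-calibration check accordingly
  averages over cohorts.
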