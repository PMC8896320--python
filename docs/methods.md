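# Methods

## PWM model and file dialects

A PWM is an L × 4 row-stochastic matrix in fixed A,C,G,T column order.
Matrices read from files are validated (non-negative, four columns, rows
summing to 1 within 1e-6 after normalization); count matrices are detected
when all cells are integral and some row sum exceeds 1.5, converted to
probabilities, and their row sums retained so that writing the collection
back reproduces the original counts exactly.  JASPAR and TRANSFAC records
are parsed with Biopython's motif parsers; writing uses in-package
formatters so integer counts round-trip verbatim.  The *plain* dialect —
an optional `>name` header and L whitespace-separated rows of 4 reals, one
PWM per file — is the interchange layout used by per-family directories.
TF symbols are recovered from PWM names by stripping a trailing
`_<digits>` suffix (ATF4 and ATF4_1 are two matrices of one factor).

Degenerate inputs: an all-zero row is an error unless a pseudocount is
given (default 1e-6 at count normalization); a malformed row fails with
the file and line number; an empty file or directory is an error rather
than an empty collection.

## Motif similarity

Columns are compared as `1 − ‖a − b‖₂/√2`, which is 1 for identical
columns and 0 exactly for maximally distant one-hot columns (√2 is the
diameter of the probability simplex under the Euclidean norm).  Motif
similarity maximizes the mean column score over all ungapped offsets, on
the forward strand and — by default — against the reverse complement of
the query, subject to a minimum overlap of `max(4, ⌈0.5·min(L_p, L_q)⌉)`
columns (clamped to the shorter motif); without the floor, one-column
overlaps would routinely score near 1.  Overhanging columns are not
penalized: the score is a mean over the overlap only.  Ties between
placements are broken toward larger overlap, then smaller absolute
offset, then the forward orientation.  The score is symmetric, lies in
[0, 1], and is invariant to reverse-complementing any input.  The n × n
similarity matrix holds these scores with an unset (NaN) diagonal until
the clustering preference fills it.

The per-column score is this package's own definition, chosen for its
closed form and [0, 1] range; the downstream defaults (notably the 0.80
good-cluster threshold) are calibrated against it.

## Affinity propagation

The standard responsibility/availability updates are iterated with
damping λ (convex mixing, new = λ·old + (1−λ)·new).  Defaults: damping
0.9, max_iter 1000, and convergence when the exemplar set
{k : C(k,k) > 0} is unchanged for 50 consecutive iterations.  The
preference (diagonal of S) may be the median of the off-diagonal scores,
their minimum, or an explicit value.  The module-level default is the
median — the conventional neutral choice; the *pipeline* default is the
minimum, because collections arriving there are typically homogeneous
within a DBD bucket, where the median similarity sits at the
within-family level and over-fragments buckets into singletons.

Two numerical details matter.  First, exact-tie degeneracies (every pair
equally similar) leave all messages at zero and no exemplar can emerge;
that case is decided directly — a preference above the shared similarity
keeps every point separate, otherwise all points merge — and general
message passing runs on S plus machine-epsilon-scale Gaussian jitter from
a fixed seed (the standard degeneracy-removal convention for these
updates), so results remain a pure function of S and the parameters.
Second, after convergence each exemplar is refined to its cluster's
medoid (the member maximizing the within-cluster similarity sum) and a
final assignment sweep maps every point to its most similar exemplar,
with exemplar self-assignment; ties resolve to the lowest index.  If no
exemplar ever attains a positive criterion diagonal, the run fails with
advice to raise the preference.

On random symmetric similarity matrices the damped iteration is
multi-stable: which of several equal-quality fixed points is reached
depends on sub-epsilon perturbations.  Sharing the jitter convention with
the reference implementation is what makes exemplar sets comparable
across implementations.

## Cluster quality assessment

Only one feature is available per cluster — its similarity submatrix — so
quality is a combination of statistical summaries of it:

* **mean score**: mean off-diagonal similarity; the cluster is labeled
  *good* when ≥ `mean_threshold` (default 0.80, inclusive), *average*
  when ≥ 0.5, *bad* below, *singleton* at n = 1.
* **Z-score filter**: each row of the submatrix is standardized using the
  population standard deviation over its n−1 off-diagonal entries
  (zero-spread rows give all-zero Z).  Entries with Z < `z_threshold`
  (default −1) are counted per column — how often the *other* members
  find PWM j dissimilar (row-wise counting is config-switchable).  The
  top ⌈`top_fraction`·n⌉ PWMs by count (default 15%, only PWMs with a
  nonzero count) are removal candidates.  A candidate is removed when its
  count reaches `max(1, ⌈support_fraction·(n−1)⌉)` (default 5%) **and**
  its own mean similarity to co-members is below `mean_threshold`.

The last gate is a deliberate design choice: standardization is
scale-free, so even a tight cluster of near-identical PWMs always has a
few Z < −1 entries, and count thresholds alone would steadily remove
members from perfectly good clusters.  A member that agrees with its
co-members at 0.95 is not poorly clustered no matter how its noise
standardizes.  With the gate, planted dissimilar members (similarity
≈ 0.2 to the family) are removed with ≈ 100% sensitivity while pure
clusters are essentially never touched; both rates are recomputed by
`scripts/acceptance.py`.  Clusters of size ≤ 2 are never filtered (the
spread is degenerate) and are labeled by mean score only.  Removal always
raises the surviving cluster's mean similarity when the removed member
was genuinely dissimilar.  An alternative parameterization (z_threshold
−1.2, top_fraction 0.05) is available through the same config fields.

A collection-level summary labels each cluster by the fraction of members
whose mean similarity to co-members reaches a cutoff (default 0.80):
*good* at ≥ 85%, *average* at ≥ 50%, *bad* below, with singletons
tallied apart — the distribution used to compare with-DBD against no-DBD
clustering.

## Representative motifs

Each surviving member is aligned to the cluster exemplar; members whose
best alignment is on the reverse strand are reverse-complemented, then
laid onto exemplar coordinates at their best offset.  Covered positions
are averaged elementwise over the members covering them (equal weights;
no information-content weighting) and renormalized; positions covered by
no member are dropped.  A cluster of copies of one matrix reproduces that
matrix exactly.

## DBD database and classification

Snapshot TSVs (tf_symbol, dbd_name) from up to three sources are merged
into one record per TF symbol with precedence tfclass > jolma > jaspar
(a higher-precedence source always wins a conflict).  Raw family names
are matched case-insensitively with spaces/hyphens/underscores stripped,
mapped through a synonym table to canonical display names, and subfamily
names are rolled up to their parent family (E2A → bHLH).  The shipped
table covers the common families (bZIP, bHLH, C2H2_ZF, HMG, T_box, RHR,
bHSH, Tryptophan, homeodomain, nuclear receptor, forkhead, ETS) and is
user-extensible; unrecognized names pass through unchanged rather than
being guessed.  TFs absent from every snapshot are assigned to the
`unknown_dbd` category — a bucket, not an error — so classification is
always a partition of the input collection.

## Ensemble motif discovery

The loop draws ⌈fraction·n⌉ sequences without replacement per repetition
(default 15%, 10 repetitions; child seed for repetition r is base + r, so
repetitions are independent and order-invariant), predicts motifs on each
subsample, pools the predictions under provenance names
(`rep<r>_L<w>_<k>`), clusters the pool, applies the quality filter when
enabled, builds representatives of the surviving clusters and searches
them against a known-PWM database.  A fixed seed and config give a
byte-identical run manifest.

The predictor is a contract — any callable from (weighted sequences,
length range, seed) to a PWM collection — so an external binding-energy
predictor can be plugged in.  The built-in `naive_predict` scores every
w-mer by its weight-summed occurrence count divided by its expected count
under a first-order Markov model fitted to the input (the analytic
equivalent of counting in dinucleotide-shuffled sequences), and seeds a
position-frequency matrix from the winner's exact occurrences.  It exists
to make the loop runnable and testable end to end; it predicts a single
sharp motif per width and is not a substitute for a probabilistic binding
model on real data.

## Synthetic study conditions

The fixture generator emulates the family structure the clustering
assumes: each family member draws its columns from a Dirichlet centred on
(1−ε)·one-hot + ε·uniform of the consensus (ε = 0.02) with concentration
50 by default — producing within-family similarities around 0.9 and
cross-family similarities around 0.4–0.6 for disjoint consensi; optional
length jitter pads or trims flanks with uniform columns to exercise the
offset search.  Planted outliers have independent random sharp columns.
Sequence sets are i.i.d. uniform ACGT backgrounds with one PWM sample
planted per selected record and log-normal weights.  Default benchmark
sizes: 6 families × 8 members for recovery, 10 + 1 members for the
filter, 200 sequences × 40 bp for the ensemble — sizes at which every
quantity in `scripts/acceptance.py` recomputes in seconds.

What passing these benchmarks does **not** show: real PWM collections
have correlated families (shared half-sites, palindromes), heterogeneous
information content and heavily non-uniform genomic backgrounds (GC
content, repeats), none of which the generator models.  The benchmarks
validate the machinery — scoring, message passing, filtering, averaging,
orchestration — not performance on any particular public motif database.

## Known limitations

* Alignment is ungapped; motifs differing by an internal indel will score
  low.
* Column scores ignore information content, so low-information flanking
  columns dilute similarity for long matrices.
* Search reports raw similarity scores without a significance calibration
  (the ≥ 0.80 convention is an annotation, not a statistical test).
* The shipped DBD synonym table is a starting point, not an authoritative
  taxonomy; provide extended snapshot/synonym tables for production use.
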