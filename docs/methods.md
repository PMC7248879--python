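# Methods

## The reduction model

An ensemble Ω_gen of decoys for one protein is reduced to Ω_red in three
stages. Structures are first mapped to 12 USR shape features — for each of
the four reference points (ctd, cst, fct, ftf), the mean, population
variance m₂ and skewness g₁ = m₃/m₂^{3/2} of the atom-distance
distribution. Distances use either all atoms in the file or CA atoms only
(`selection`); the default is all atoms, with `ca_only` offered because
de-novo decoys are often coarse-grained. Skewness is defined as 0 when
m₂ < 1e−12 (degenerate distributions). The descriptor is exactly invariant
to rigid motion and to atom order except through reference-point
tie-breaking, which resolves to the lowest atom index for determinism.

Clustering operates on these 12-vectors, raw (no standardization; an
explicit scaling step can be applied by the caller). Four algorithms are
provided; each carries its own model-selection rule so no k is supplied by
hand:

* **k-means.** For each k in the search range, 10 restarts are initialized
  at k distinct structures drawn uniformly at random; each restart is
  scored by the within-cluster scatter L(C) = ½ Σ_l Σ_{i≠j∈C_l} ‖x_i−x_j‖
  (unsquared distances, each unordered pair once) and the minimizer kept.
  The SSE of the winning run is recorded per k and the final k sits at the
  knee of the SSE curve: the point of maximum perpendicular distance to
  the chord joining the curve's endpoints, ties to the smallest k. The
  k = 1 SSE (about the global centroid) is prepended to the curve because
  chord endpoints have zero distance by construction — without it a knee
  at the smallest clusterable k (k = 2) could never be detected.
* **Gaussian mixture.** EM per k (regularization 1e−6 on covariance
  diagonals, full covariance by default, diagonal available for small n),
  k at the BIC minimum. The default BIC penalizes the number of free
  mixture parameters (means + covariances + weights), the convention of
  mainstream statistical practice; a `literal` mode penalizes the bare
  component count, ln(n)·k − 2 ln L̂, for comparison. The literal penalty
  is far weaker and tends to overfit k; it is provided for completeness,
  not as the default.
* **Single-linkage agglomerative.** The dendrogram is built once; each
  candidate k (default grid 2..min(100, n−1), in place of evaluating every
  one of the n−1 merge heights, which costs quadratic work for no stated
  benefit) cuts it into k clusters, and the cut minimizing the
  Davies–Bouldin index — mean over clusters of the worst
  (σ_i+σ_j)/d(c_i,c_j) ratio, σ the mean member-to-centroid distance —
  wins, ties to the smallest k. Distinct clusters with identical centroids
  make DB undefined; such cuts raise an error (or are skipped with a
  warning inside the model-selection loop).
* **Greedy USR-cutoff (gmx-cluster style).** Pairwise USR distances are
  normalized to [0, 1] by dividing by the ensemble's maximum pairwise
  distance (the constant is recorded as `raw_max`); repeatedly, the
  structure with the most neighbors within the 0.1 cutoff becomes a
  center and is removed together with its neighbors. Deterministic,
  seed-free; ties to the lowest index.

The selector groups each cluster's structures into energy levels: bin key
= round-half-even(energy / width), width 0.01 REU by default so energies
identical to two decimals share a level (truncation-toward-zero keying is
available as an alternative, the choice between the two being genuinely
open). One member per non-empty (cluster, level) is drawn uniformly at
random under a dedicated seed. Two bounds follow by construction and are
asserted in the tests: the minimum energy of Ω_red exceeds that of Ω_gen
by less than one bin width, and the energy diameter shrinks by less than
two. The truncation baseline keeps the M lowest-energy structures (stable
on ties); its min-energy difference is exactly 0. When several cluster-based
reductions exist, `auto_truncation_size` sets M to their maximum size so
the baseline is never disadvantaged by a smaller budget.

Evaluation uses Kabsch superposition over CA atoms (proper rotations only,
determinant +1 enforced — a physical chain cannot be reflected), population
standard deviations throughout (the estimator choice is unstated in common
practice; population is used consistently for lRMSD and energies), and
reports difference columns as absolute magnitudes. The USR–lRMSD Pearson
correlation uses raw feature-space distances; r is invariant to the
positive scaling normalization would apply.

## Synthetic ensembles

The generator emulates the two statistical properties the method assumes
of real decoy sets: a multi-basin structure space and energies that
correlate only weakly with nativeness. A self-avoiding random walk with
exact 3.8 Å CA–CA steps, turns bounded at 90°, and ≥ 4 Å clearance between
non-consecutive atoms serves as the native. G basin seeds are Gaussian
perturbations of the native (per-coordinate σ_c, default 6 Å); members
perturb their seed (σ_m, default 0.3 Å, giving 20× separation-to-jitter in
coordinate space); energies are e₀ + slope·lRMSD + N(0, σ_E), defaults
−150 REU, 2 REU/Å and 3 REU — a funnel noisy enough that energy rank is an
unreliable nativeness rank, which is the regime the selector is built for.
Defaults produce 4 × 50 structures on a 60-residue chain; tests and the
acceptance script scale the member counts (up to 4 × 500) without touching
the statistical parameters.

What the generator does not emulate: secondary structure, torsional
geometry, side chains, or force-field ruggedness. Passing tests demonstrate
the reduction machinery's contracts, not force-field behavior.

**A property worth knowing:** USR is a lossy shape summary, so basins
separated in coordinate space need not be separated in feature space —
measured feature-space separation ratios for the default generator vary
between roughly 3 and 16 across seeds even though the coordinate-space
ratio is fixed at 20. Clustering therefore recovers the planted partition
approximately (ARI typically ≥ 0.8 via the Gaussian mixture) rather than
perfectly, and the planted-recovery guarantees are stated, and tested,
in the space being clustered: Gaussian clusters planted directly in the
12-dimensional feature space at equal pairwise centroid separations of
10× the within-cluster spread (a regular simplex). Equidistant planting
matters for the k-means knee specifically: when pairwise separations are
very uneven, the SSE drop from resolving the two closest planted clusters
is invisible on the scale of the whole curve and the chord rule
(correctly) reports the knee earlier — a known limitation of elbow-style
selection, not of this implementation.

## Numerical choices and degenerate inputs

Ties everywhere break to the lowest index / smallest k. Identical
duplicated points in k-means may yield fewer effective clusters than
requested; labels are relabeled contiguously and k reported as the number
of distinct labels. An all-identical ensemble produces a zero USR score
matrix with a logged warning. Knee detection requires ≥ 3 curve points and
falls back (with a warning) to the smallest interior k on a straight
curve; a single-candidate k range skips model selection. PDB coordinates
round-trip at the format's fixed-width precision, 1e−3 Å. Energy bin keys
use numpy's round-half-even, so level membership is reproducible across
platforms.

## The truncation coverage-loss experiment

The diagnostic that truncation loses near-native structures needs the
noise-dominated regime: the experiment uses slope 0.25 REU/Å against
σ_E = 6 REU (correlation between energy and lRMSD ≈ 0.1) and bin width
0.5 REU so the selector actually shrinks the ensemble (to ~45%), making
truncation discard the complement. Under these conditions the structure
closest to the native carries essentially random energy rank, so
truncation drops it in roughly the fraction of runs equal to the discard
rate — a majority of seeds at these settings, with the per-(cluster,
level) selector's gap at 0 in most runs. The quantity is reported as a
diagnostic; its value fluctuates around the majority line across seed
sets, as a near-coin-flip Bernoulli fraction over 15 replicates must.

## Problem sizes

Tests and the acceptance script use ensembles of 80–2,000 structures on
30–60-residue chains, 200 random score matrices of size ≤ 30 for oracle
equivalence, and 20 replicates per condition for recovery studies —
desk-scale versions of the method's intended inputs chosen so the full
suite completes in a couple of minutes.

## Known limitations

USR degeneracy (distinct conformations, similar moments) bounds what any
clustering in this space can resolve; chirality is invisible to USR.
Normalization of USR scores by the ensemble maximum makes scores — and
hence the 0.1 cutoff's meaning — ensemble-relative. Atom pairing for lRMSD
is positional (same protein assumed; no sequence alignment). The energy
model consumes energies as input and never computes them.
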