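# Methods

This note documents the statistical procedures implemented in `ssrsa`, the
assumptions behind them, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Representational dissimilarity

An RDM over `n` conditions stores pairwise Pearson correlation distances
`1 − r` (range [0, 2], zero diagonal, symmetric).  A response row with zero
variance makes the distance undefined and is treated as an error naming the
condition — silent NaNs would poison permutation nulls downstream.  RDMs are
vectorised row-major over the upper triangle (`d12, d13, …, d23, …`), the
fixed order making stored vectors portable; `rdm_from_upper` is the exact
inverse.  RDM pairs are compared by Spearman's ρ with average (mid) ranks for
ties, the standard definition; a constant RDM vector is an error rather than
a NaN.  Rank correlation makes every comparison invariant under strictly
increasing transforms of either RDM, which is what lets model and brain
dissimilarities, on very different scales, be compared at all.

## Model timelines and frame bookkeeping

Acoustic analysis frames are 25 ms long and shifted by 10 ms; frame `t`
covers `[10t, 10t + 25)` ms.  Three operations assemble network-input-like
feature vectors:

- **Delta augmentation** appends the central difference
  `(o[t+1] − o[t−1]) / 2` with duplicated boundary neighbours, doubling the
  dimension (40 → 80).  The ±1-frame support is the unique choice consistent
  with a 125 ms effective receptive field once nine frames are stacked: nine
  frames span 105 ms and the derivative adds one 10 ms frame per side.
- **Context stacking** concatenates frames `t−4 … t+4` with out-of-range
  indices clamped (boundary duplication), giving `9 × 80 = 720` dimensions.
- **Frame reservation** keeps index `t` when `10t + 25 ≤ D_min` (shortest
  stimulus duration), i.e. `floor((D_min − 25)/10) + 1` frames — 27 at
  285 ms.  The half-open-window formula is normative here; counting frames
  that merely *start* before `D_min` would give a different count and is not
  used.

A model RDM stream has one RDM per reserved frame (stream times `10t` ms),
built from all conditions' frame-`t` activation vectors.  For input-layer
(filterbank) streams only the bare 40 base values of the central frame are
used — no deltas, no context — which `fbk_stream_select` recovers from the
stacking metadata.

## Searchlight and latency matching

A searchlight patch is every vertex within `radius_mm` (default 20 mm,
Euclidean in 3-D coordinates) of the centre, restricted to the centre's
hemisphere.  Euclidean rather than geodesic distance is the common
searchlight convention and is well-defined on any vertex cloud; geodesic
distance would differ on highly folded real cortex but not qualitatively on
the synthetic meshes used here.  The temporal window is half-open,
`[t, t + 25)` — 25 one-millisecond samples — stepped by 10 ms over a
`[0, 540)` ms epoch: starts `t = 0, 10, …, 510`.  The response vector per
condition concatenates samples patch-vertex-major; its correlation-distance
matrix is one brain RDM frame.

The latency sweep correlates model frame τ with the brain window at
τ + k for `k = 0 … 250 ms` in 10 ms steps, averaging Spearman ρ over all
fully alignable (τ, τ+k) pairs — truncation at stream ends, no padding.  With
a 27-frame model stream and 52 windows every k on the default grid aligns
all 27 pairs.  Per-subject ρ-maps are the primary objects; subjects combine
by a one-sample t-test (`mean / (sd/√n)`, `n−1` denominator) per cell, as the
random-effects permutation scheme requires.  Cross-subject RDM averaging
(`average_rdms`) is available as a primitive for fixed-effects exploration
but yields no group inference.  If all subjects report the identical ρ at a
cell the t-statistic is undefined; a bounded sentinel ±100 is substituted and
flagged (`TMap.zero_variance`).  The bound keeps the TFCE threshold loop
finite; with continuous noisy data the case never occurs.

### Performance path

`all_subject_rho_maps` computes, per vertex and window, the condition
cross-product and sum statistics once, and sums them over each patch —
neighbouring patches overlap heavily, so this shares most of the work — then
rank-transforms all window RDM vectors per subject in one batch (one argsort
when a row has no ties, `scipy.stats.rankdata` for tied rows).  The reference
implementations (`brain_rdm_stream` at one centre, `subject_rho_map` per
subject) recompute everything from scratch and the test suite checks
agreement: exact in double precision, ~1e−6 for single-precision epochs.

## TFCE and corrected inference

The enhanced value of a cell with statistic `t ≥ 0` is
`Σ_{i≥1, i·Δh ≤ t} (i·Δh)² e(i·Δh)` with `Δh = 0.1`, where `e(h)` is the
extent of the cell's connected component among cells `≥ h` on the
spatiotemporal graph (mesh edges at equal latency plus same-vertex edges
between consecutive latencies; no diagonal links — the minimal standard
choice).  Three deliberate choices:

- The sum is evaluated literally on the threshold grid without the Riemann
  factor Δh.  The missing constant is a uniform monotone scale: maxima,
  cluster shapes and permutation p-values are unchanged.
- Negative t gets enhancement 0; the hypothesis (positive model–brain
  correlation) is one-sided.
- The exponent pair (height², extent¹) is fixed, not parameterised.

The implementation processes thresholds in descending order with a
union-find over activating cells (a numba kernel), accumulating each cell's
`h²·e(h)` terms from its own value downward; the test suite verifies exact
float equality against a brute-force oracle that re-enumerates components at
every threshold independently.  Enhancement is monotone along graph edges
(`t_u ≤ t_v` adjacent ⇒ `TFCE_u ≤ TFCE_v`), so locations of weak local maxima
are preserved; `isocontour_check` verifies exactly this — no adjacent pair
strictly reordered, every weak local maximum preserved.  Note that the
*global* argmax within a connected region is **not** mathematically invariant
under TFCE (a broad plateau can out-enhance a narrow higher peak), so the
check is deliberately stated in terms of adjacent ordering and local maxima,
which are the guarantees the transform actually makes.

Corrected inference: one random ±1 per subject per permutation (shared
across all cells and both hemispheres, preserving within-subject spatial
covariance), group t-map recomputed — only the flipped sums need
recomputation, since Σρ² is flip-invariant — enhanced, and the per-hemisphere
map maximum recorded; 1,000 permutations by default.  A cell's corrected p is
`(1 + #{null maxima > observed}) / n_perm`, clamped to 1: strictly-greater
counting with +1 in the numerator, the convention that makes an observation
beating all 5,000 nulls report exactly `p = 0.0002` (see clustering below).
Cells at `p < α` (default 0.01) are grouped into connected components; the
summary statistic is the maximum over latencies of the total suprathreshold
extent, summing spatially discontinuous clusters.

**What the correction controls.** Null distributions are collected per
hemisphere and each hemisphere's map is compared to its own null, so the
controlled family is one hemisphere's (vertex × latency) map.  Two
independent hemisphere-level tests at α jointly flag *something anywhere*
at rate `1 − (1−α)² ≈ 2α`; whole-brain control would require a single null
over the cross-hemisphere maximum (or halving α).  The calibration test and
the acceptance script report the per-hemisphere family-wise rate (and the
script additionally reports the whole-map rate for transparency).

## Clustering evaluation

Per-frame activations within a contiguous phonetic segment are averaged (a
frame belongs to the segment containing its window midpoint `10t + 12.5` ms),
one vector per segment — repeated phones in a word stay separate.  Five
labeling schemes assign each vector a label: phone identity (all phones),
place and manner of articulation (obstruents only), vowel frontness and
closeness (syllabic vowels only).  The shipped phone → feature table is a
synthetic stand-in with standard phonetic assignments, one label per
applicable phone; schemes left with fewer than two labels after the
applicability filter are flagged rather than scored.

The Davies–Bouldin index uses Euclidean geometry: cluster scatter `s_k` is
the mean distance of members to their centroid and
`DB = (1/K) Σ_k max_{j≠k} (s_k + s_j) / d(c_k, c_j)`.  The "closest
neighbouring cluster" is realised as the ratio-maximising partner — the
standard form of the index.  Zero is attained only when labels are shared
only between identical points.  Coincident centroids make the index
undefined: an error for a direct call, but inside the permutation null a
shuffled labeling with coincident centroids is an infinitely bad clustering
and counts as "not more extreme".  The permutation p-value shuffles the label
multiset over segment vectors (default 5,000 times); lower indices are more
extreme, ties do not count, `p = (1 + #lower)/n_perm` clamped to 1.

Sammon MDS minimises `E = (Σδ)⁻¹ Σ_{i<j} (δ_ij − d_ij)²/δ_ij` by gradient
descent from a seeded random start, halving the step on any stress increase
(stress is non-increasing over accepted iterations) and growing it mildly on
success.  Zero off-diagonal input distances are an error — the 1/δ weight is
undefined.

## Synthetic data: what is emulated, what is not

The generator produces all four pipeline inputs with controllable planted
structure.

**Mesh**: two Fibonacci-sphere point sets (seeded random rotation) scaled to
`mesh_radius_mm`, triangulated by their convex hull (the spherical Delaunay
triangulation), offset ±2 radii along x.  Connected, degree ≥ 3, no
cross-hemisphere edges.  It does not emulate cortical folding, so Euclidean
and geodesic patches nearly coincide — conclusions about patch shape on real
cortex do not follow.

**Segments and activations**: random contiguous segmentations (40–90 ms
segments, each containing at least one frame midpoint) with phones drawn from
the stand-in inventory; per layer, one centroid per scheme label with
magnitude ∝ `cluster_separation`, frames = centroid + isotropic Gaussian
noise (`noise_sd`).  Real activations have temporal autocorrelation within
segments and non-isotropic covariance; passing tests show the index and its
null behave correctly, not that real layers cluster.

**Source epochs**: for each reserved model frame τ the target correlation
matrix `C_τ = 1 − RDM_τ` is factored (eigenvalue square root, clipped at 0)
and mapped through a shared orthonormal basis whose columns are orthogonal to
the constant vector, giving per-condition pattern rows with *exactly* the
target correlations and zero mean.  Patterns occupy the effect vertices in
5 ms blocks under a period-5 column schedule: because a 25 ms window stepped
by 10 ms covers five consecutive blocks, every window sees a full column
permutation of one pattern matrix.  When the target stream is locally
constant the window RDM is exact (the noise-free tests exploit this); when
the stream varies, windows blend adjacent frames — an intentional smoothing
comparable to real temporal integration.  The planted signal (unit scale) is
mixed as `effect_size · pattern + (1 − effect_size) · noise` at effect
vertices; everywhere else, and outside the planted interval, is i.i.d.
Gaussian noise with `noise_sd`.  The noise model is a stand-in: real source
estimates have strong spatial and temporal correlation from the inverse
operator, so the calibration results here demonstrate correctness of the
inference machinery under exchangeability, not its behaviour under realistic
noise covariance.  Epochs are generated in single precision (half the memory
traffic; the rank statistics are insensitive at 1e−6).

**Defaults as study conditions**: 40 conditions with durations 285–505 ms
(shortest pinned at 285 ms so 27 frames are reserved), 6 subjects, 160
vertices per hemisphere at 50 mm radius, a compact 6-vertex effect cluster
in the left hemisphere (6 × 25 samples ≥ 41 pattern dimensions, the minimum
for 40 conditions), planted latency 70 ms, `effect_size 0.8`,
`noise_sd 1.0`, `cluster_separation 2.0`, eight layers
(40/100×5/26/50 nodes).  These sizes keep a full replicate around ten
seconds on one CPU while leaving the planted effect well inside the
recoverable regime; with `effect_size 0.8` the expected searchlight ρ at the
planted site is ≈ 0.5–0.8 against a null spread of ≈ 0.1.

Everything draws from named sub-streams of a single seed
(`ssrsa._rng.substream`), so each component is bit-reproducible in isolation
and identical configs produce identical outputs.

## Known limitations

- Euclidean-only patch distance (geodesic would require the mesh metric).
- The Gaussian noise model understates spatial correlation of real source
  estimates; family-wise calibration on real data should be re-checked.
- Only the `h²·e` TFCE form is implemented; the general (E, H) parameterised
  family is out of scope.
- Fixed-effects (subject-averaged RDM) mapping is available only by
  composing `average_rdms` with the stream comparison functions; the
  pipeline's inferential path is per-subject ρ-maps by design.
- Sammon embedding uses plain gradient descent with step halving; for large
  point sets a second-order scheme would converge faster.
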