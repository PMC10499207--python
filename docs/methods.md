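# Methods

`funcgeo` implements a resting-state functional-geometry analysis for
multichannel intracranial electrophysiology: band-limited functional
connectivity, diffusion map embedding (DME) of the thresholded
connectivity graph, and a battery of downstream statistics (hierarchical
clustering with bootstrap stability, hub scoring, permutation tests on
embedding distances, hemispheric scaling, signal-to-noise).  Everything is
exercised end to end on synthetic cohorts with planted ground truth.

## Signal model and preprocessing

A recording is a channels × samples voltage array with per-channel
metadata (participant, ROI, hemisphere).  The cleaning cascade:

1. **Channel rejection.** A channel is dropped if its average log band
   power in *any* canonical band — broadband, delta (1–4 Hz), theta
   (4–8), alpha (8–13), beta (13–30), gamma (30–50), high gamma
   (70–110) — exceeds the across-channel mean by more than 3.5 SD.  The
   broadband range is taken as 1–110 Hz.  Note that a lone outlier among
   M channels can reach at most (M−1)/√M SDs of a statistic that includes
   it, so the rule only bites at realistic channel counts (tens per
   participant).
2. **Transient masking.** Deflections exceeding 10 SD (strictly) are
   extended to the surrounding zero crossings of the demeaned trace and
   padded by 100 ms on each side.  Ties at the threshold are not masked
   (a measure-zero event; strictness keeps behaviour deterministic).  A
   constant channel (SD = 0) is flagged unusable.
3. **High-gamma masking.** Frames whose 70–110 Hz power exceeds the mean
   by 5 SD are masked.
4. **Joint application.** Masks are applied across channels
   simultaneously: a time bin enters the analysis only if it is clean on
   every retained channel.  Because dropping a noisy channel can recover
   time on all others, a greedy loop removes channels while doing so
   increases the retained channels × samples count.
5. **Common-signal removal.** Shared broadband noise (equipment, muscle,
   reference contamination) is removed with a spatial filter
   `W = S (I − u₁u₁ᵀ) S⁻¹`, where `S = diag(1/σᵢ)` holds inverse channel
   SDs of the > 200 Hz high-passed data, and `u₁` is the first
   eigenvector of its normalized covariance.  High-passing first keeps
   slow physiological correlations out of the estimate while preserving
   the zero-lag structure of the artifact.  `S⁻¹WS` is a rank-(M−1)
   projector (one zero eigenvalue, rest exactly one).

**Filtering.** All band definitions use 4th-order Butterworth responses.
Zero-phase filtering is applied spectrally: the rfft of the signal is
multiplied by |H(f)|², the squared magnitude response, which is exactly
the magnitude response of forward–backward (filtfilt) application.
Differences from time-domain filtfilt are confined to edge handling
(circular rather than reflective), negligible for the long segments used
here, and the spectral route is an order of magnitude faster on
10-minute recordings.  The analytic band signal is obtained in the same
FFT pass (one-sided spectrum inversion), and decimated to the 50 Hz
envelope frame rate by folding the band spectrum before the inverse
transform — algebraically identical to computing the full-rate analytic
signal and striding, which a unit test verifies to machine precision.
50 Hz frames comfortably oversample the 0.2–1 Hz envelope content.

Band envelopes are the log squared analytic amplitude with a relative
floor of 1e−12 × median power, so silent bands stay finite.

## Connectivity

**Orthogonalized power envelope correlation.** For analytic signals X, Y
of one band, Y is orthogonalized to X as `Y_orth = |Im{Y·X*/|X|}|`,
which discards the component of Y exactly in phase with X and hence the
zero-lag (volume-conducted) contribution.  The log-power envelopes of X
and Y_orth are bandpass filtered to 0.2–1 Hz and Pearson-correlated; the
procedure is repeated with roles swapped and the two correlations
averaged.  A pair whose orthogonalized signal is numerically zero (an
exactly in-phase copy) carries no orthogonalized evidence; it returns 0
rather than NaN, which downstream thresholding treats as the weakest
edge.  Estimates are formed in 60-second segments and averaged; trailing
partial segments are discarded.

**Debiased wPLI.** Per segment, cross-spectra are computed in 1-s Hann
windows (50 % overlap); the debiased weighted phase-lag-index square
estimator is formed from the imaginary parts across windows at each
frequency, averaged across in-band frequencies, then across segments.
Values can be slightly negative by construction and are not clipped.

**Pearson connectivity** serves the slow (BOLD-like) ROI-series
comparator path.

**ROI aggregation and coverage.** ROI-pair connectivity is the mean over
all cross-site pairs; the within-ROI entry uses cross-site pairs only,
so single-site ROIs have an undefined (missing) diagonal.  For group
summaries, ROIs are pruned greedily until every retained pair is sampled
by at least 2 participants (ties broken by fewest sufficiently covered
partners, then fewest sampling participants, then name).  The group
matrix is the entrywise mean over participants sampling each pair.
Group averaging happens on connectivity, and one diffusion operator is
built from the averaged matrix; averaging the per-participant operators
instead is available through the same functions applied per participant.

## Diffusion map embedding

The connectivity matrix is sparsified by keeping, per row, the top
⌈(n−1)/3⌉ entries (ties: value descending, then column index), the
transpose of that mask, and all edges of the minimum spanning tree of
the elementwise-reciprocal weight graph — guaranteeing a single
connected component whenever the input graph is connected.  Cosine
similarity between thresholded rows yields the kernel K; the two
self-connectivity positions are excluded from each row comparison by
default (switchable), and negative cosines (possible with wPLI input)
are floored at 0 to keep K a valid random-walk kernel.

With degrees `D = diag(K·1)`, the random-walk operator is `P = D⁻¹K` and
its symmetric form `Psymm = D^−1/2 K D^−1/2`; they share eigenvalues,
and the orthonormal eigenvectors `v_j` of Psymm give right eigenvectors
of P.  Coordinates use `ψ_j = sqrt(Σd) · D^−1/2 v_j`, a scaling chosen
so that Euclidean distance in the full embedding
`Ψ(t) = [λ_j^t ψ_j]` equals the t-step diffusion distance

    D_t²(i,k) = Σ_j (P^t[i,j] − P^t[k,j])² / π_j,

with π the degree-normalized stationary distribution — verified against
a brute-force matrix-power oracle to 1e−8 on graphs up to n = 50.  The
trivial constant eigenvector (λ = 1) is dropped before dimensions are
indexed.  Eigenvector signs are fixed by making each vector's
largest-magnitude component positive.  Results are reported at t = 1;
the multiscale variant scales dimension j by λ_j/(1−λ_j), the geometric
sum of λ^t over all positive t, and on planted-structure graphs its
distance geometry correlates r > 0.99 with t = 1.

**Dimension selection.** The best rank-k approximation to P has spectral
error σ_{k+1}, so the sorted eigenvalue-magnitude curve measures the
payoff of each extra dimension.  The elbow `k_infl` is the point of
maximum vertical distance below the chord of the normalized curve
(kneedle-style); `k_infl − 1` dimensions are retained (floored at 1;
flat spectra fall back to k = 2 with a warning).  For a curve with a
genuine slope break the detected elbow is independent of how long the
shallow tail is; for featureless curves (pure geometric decay) the
detected index necessarily drifts with spectrum length — there is no
distinguished point on a self-similar curve — so only break-type spectra
are treated as meaningful elbows.

**Change of basis.** Embeddings of the same node set from different
cohorts, conditions, or bootstrap resamples live in eigenbases that
differ by sign flips and rotations within near-degenerate eigenspaces.
The mapping computes the overlap of target and reference eigenvectors,
takes its nearest rotation (SVD polar factor), and applies it in
coordinate space.  This is the identity when target equals reference, is
an exact isometry (pairwise distances are untouched, so distance-based
analyses need no mapping at all), and reduces to sign alignment in the
generic well-separated case.  A raw Nyström projection onto the
reference eigenvectors is not an isometry when the degree matrices
differ, which is why the rotation form is used.

## Mesoscale structure

Ward-linkage hierarchical clustering (Euclidean metric) runs on the
retained embedding coordinates, with leaf order optimized over the fixed
tree topology (scipy's distance-minimizing ordering; merge heights are
unaffected).  Global stability across cluster bootstrap iterations uses
the Fowlkes–Mallows pair-counting index `B_k = T_k/√(P_k Q_k)`,
normalized by its chance expectation under permutation with fixed
marginal cluster sizes, `E(B_k) = √(P_k Q_k)/M` (hypergeometric
expectation of shared pairs), as `(B_k − E)/(1 − E)`: 0 at chance, 1
when identical.  Per-cluster stability is the median over iterations of
the maximum Jaccard coefficient against each bootstrap labeling, minus a
bias estimate obtained by permuting the bootstrap cluster assignments.

Hubs are scored geometrically: per node, the Euclidean distance to the
embedding centroid (over retained dimensions), the mean off-diagonal
connectivity, and the centroid distance normalized to the within-band
median.  Strongly, homogeneously connected nodes sit near the centroid,
producing a strong inverse relation between centroid distance and mean
connectivity on networks with graded hubness.

## Inference

**Cluster bootstrap.** Recording sites are nested in participants, so
participants are the resampling unit: each iteration resamples them with
replacement, re-averages ROI connectivity, re-embeds, and maps the
result to the reference basis; per-ROI coordinate SDs (ellipsoid
semiaxes) and per-pair distance spreads summarize the ensemble.
Resamples that break pair coverage are redrawn and counted.  The default
iteration count is 1,000 (configurable); the estimates are stable well
below that at cohort sizes used here.  On dense (unthresholded) graphs
the coordinate SDs scale as 1/√N with cohort size; under the hard
top-third threshold an additional discrete component — edges flipping in
and out of the mask — floors the SD at small noise levels, a known
property of hard sparsification rather than of the bootstrap.

**Permutation tests.** All p-values are `(1 + exceedances)/(n_perm + 1)`
and respect the corresponding floor.  The set-distance test compares two
nodes' average distances to a target ROI set, with the null built by
exchanging the two labels independently per participant (sign flips).
The hemisphere location test compares per-node displacement between
cohort-average embeddings, permuting cohort membership.  The hemisphere
scaling test regresses one cohort's pairwise distances on the other's
through the origin (the natural model for a multiplicative effect; OLS
with intercept is a one-line alternative), tests slope ≠ 1 by
permutation at the participant level, and tests per-pair residuals after
dividing out the slope, with Benjamini–Hochberg FDR per analysis family.
Type-I calibration is measured on label-exchangeable synthetic
embeddings and distance matrices — the tests operate downstream of
embedding, so exchangeability is the only property the null requires —
giving rejection rates within [0.03, 0.07] at α = 0.05 over 500 runs.

**SNR.** Per participant, connectivity and its embedding distance matrix
are computed per 60-s segment; signal is the SD of the across-segment
mean matrix's off-diagonal entries, noise the per-element SD across
segments, averaged.  The retained dimensionality is fixed across
segments (chosen from the segment-mean spectrum) so segment-to-segment
variation reflects data, not dimension choice.  Zero noise (identical
segments) reports a capped sentinel and a flag.

**Auditory responsiveness.** Per site, trial-mean high-gamma power in
early (50–350 ms) and late (350–650 ms) windows is compared with the
prestimulus baseline (−200 to −100 ms) by one-tailed Mann–Whitney U
(response > baseline), FDR-corrected across sites within each window
family; results are percent significant sites per ROI.  Sites with fewer
than 10 trials are excluded.

**Anatomical regression.** Per node, embedding distances to all other
nodes are regressed on anatomical distances; adjusted r² per node and
its mean are reported.

## Synthetic cohorts

The generator plants the statistical structure the pipeline is designed
to detect, with defaults that define the standard study conditions:
8 participants, 16 ROIs with 1–3 sites each, 600 s at 500 Hz (a
desk-scale rate; clinical systems sample faster, and `fs` is
configurable), two equal ROI communities, within/between envelope
coupling 0.8/0.1.

Each channel is a sum over bands of unit-variance band-limited Gaussian
carrier noise (spectral synthesis) amplitude-modulated by a log-normal
slow envelope.  The log-envelope mixes three unit-variance 0.2–1 Hz
latents — global, community, private — with weights √b, √(w−b), √(1−w),
so planted log-envelope correlations are exactly w within and b between
communities.  Hub ROIs couple evenly to all community latents.  Carriers
are channel-private (random phase), so planted coupling survives
orthogonalization; entries in the phase-lag map share a carrier between
two ROIs at a fixed phase offset to drive the phase-lag index.  The
measured envelope correlation is an attenuated, monotone image of the
planted one (carrier log-power noise adds in-band variance), which is
sufficient for every recovery test and verified as a Spearman-monotone
relation across coupling levels.

The hemispheric effect is planted as a coupling-contrast change: the
nondominant half of the cohort has its within−between contrast
multiplied by `hemisphere_scale`, shrinking planted between-community
embedding distances.  Because cosine similarity normalizes row profiles,
the realized distance-scaling is much closer to 1 than the coupling
contrast (slopes ≈ 0.97–0.99 for a 0.8 contrast factor) but reliably
below 1 and significant — the recovery claim is direction, not
magnitude.  The literal multiplicative factor is additionally verified
at the distance level, where a planted 0.8 factor is recovered as a
slope within [0.75, 0.85].

Artifacts are injected at logged positions: 40-ms biphasic transients
(amplitude in per-channel SD units), 200-ms 90 Hz bursts, and a
continuous shared broadband component with per-channel gains.  Zero
rates return the input unchanged; every event is logged exactly once
with channel, onset and duration.

`planted_hub_connectivity` generates connectivity-level hub networks
directly: nodes carry community-affinity profiles, connectivity is the
scaled inner product of profiles, and a node's hubness mixes its profile
toward uniform.  Node 0 is fully uniform (the hub); the rest draw
hubness from [0, 0.7).  This yields both perfect rank-1 hub recovery by
centroid distance and the strong pooled inverse relation (Spearman
< −0.7) between centroid distance and mean connectivity.

**What the generator does not emulate:** realistic 1/f spectra (carriers
are flat within bands), volume conduction via a forward model (only
additive zero-lag common components), nonstationarity beyond the slow
envelopes, or spatially correlated artifact topographies.  Passing tests
therefore certify the statistical machinery — estimator identities,
recovery of planted effects, calibration — not performance on clinical
recordings.

## Problem sizes and numerical choices

Test and acceptance runs use the default cohort conditions (8 × 600 s,
gamma band for the community analyses: carriers in other bands are
independent of the gamma analysis and are omitted where only gamma is
analyzed).  Spectral identities are checked on 100 random graphs
(n ≤ 50) at 1e−8, threshold connectivity on 1,000 random matrices,
calibration on 500 null cohorts at n_perm = 500, recovery statistics on
20–50 planted instances.  Tolerances: operator identities 1e−8 to
1e−10; envelope nulls |r| < 0.1 at 10 minutes; planted-slope recovery
±0.05.  Degenerate inputs are handled explicitly: zero-variance channels
are flagged unusable, in-phase pairs return 0, disconnected kernels
raise, flat spectra fall back with a warning, and all-tied power
comparisons yield p = 1.

## Known limitations

- The self-excluding cosine can isolate nodes on very small or very
  sparse graphs (rows left without common support); the operator
  constructor rejects such kernels rather than silently imputing.
- The hard threshold makes bootstrap coordinate spreads piecewise
  discrete at small noise (see above).
- The end-to-end hemispheric slope compresses toward 1 under cosine
  normalization; magnitude recovery requires working at the distance
  level.
- EDF ingestion is read-only interoperability via MNE and assumes the
  channel metadata is supplied separately; BIDS-iEEG ingestion is an
  extension point, not implemented.
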