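# Methods

## Data and tree model

A spatial lineage tracing experiment follows one progenitor cell for a
duration τ_end (time-lapse frames in the motivating technology), recording
(i) the CRISPR-edited states of K target sites and (ii) the 2D position of
every cell alive at τ_end. The underlying cell lineage tree is rooted,
with a unifurcating root (the progenitor needs time before its first
division) and strictly bifurcating divisions below it; branch lengths
measure time. Because all sampled cells are contemporaneous, every
root-to-leaf path sums to τ_end exactly — fits enforce this constraint by
construction, not by penalty. Child order in Newick is meaningful: the
first-listed daughter of a division carries displacement sign +1, the
second −1. The convention is arbitrary (the likelihood is invariant to
swapping the daughters while rotating that division's angle by π) but must
be stable, and it is preserved through I/O round trips.

## Spatial model

Conditional on the division angles {θ_u}, each coordinate axis of the leaf
positions is multivariate normal: the mean accumulates the signed
displacements ±r(cos θ_u, sin θ_u) along the root-to-leaf path (the root's
own edge contributes diffusion only — the progenitor does not divide at
time 0), and the covariance of two leaves is σ² times the root-to-LCA
time. Two evaluation paths exist and are cross-checked to 1e-8 (in
practice they agree to ~1e-12):

* a dense path building the N×N covariance and using a Cholesky solve and
  log-determinant (never an explicit inverse);
* a linear-time Gaussian pruning that passes (conditional mean, extra
  variance) messages rootward, contributing one contrast factor per
  division.

**Latent-displacement (marginal) likelihood.** The per-division angles are
nuisance parameters — one per internal node, each informed by essentially
one 2D contrast. Maximizing over them jointly with σ overfits: each
fitted direction absorbs about one degree of freedom of the 2N-dimensional
location data, deflating σ̂ by ~35% at the benchmark conditions and
dragging co-estimated node times. The default fit therefore integrates
the displacements out: with orientations uniform on [0, 2π), a
displacement of length r has zero mean and variance r²/2 per axis, so the
displacement at each division is modeled as a latent isotropic Gaussian
vector with exactly those second moments. The model remains multivariate
normal with zero displacement mean and covariance σ²Σ_time + (r²/2)G,
where G is the division-coancestry matrix (+1 per shared division on the
same daughter side, −1 on opposite sides). In the pruning recursion this
adds r²/2 to each daughter's variance with a −r²/2 sibling covariance.
The approximation replaces the circle-supported displacement by a
moment-matched Gaussian; since the implied covariance equals the true
covariance exactly, the Gaussian quasi-score for σ² stays unbiased, and
the measured residual effect on σ̂ is about −0.05 at the benchmark
conditions. Reported angles after a marginal fit are the conditional-ML
angles given the fitted times and rates (a cheap secondary optimization);
`angle_mode="conditional"` instead optimizes the angles inside the joint
objective, reporting a REML-style dof-corrected σ̂
(σ̂_ML·√(2N/(2N−p)), p = root coordinates + number of angles).

**Restricted (REML) spatial likelihood.** A freely estimated root location
is nearly collinear with the diffusion accumulated on the progenitor's
first edge — a variance component shared by all leaves — and estimating it
deflates σ̂ (measured: 1.33 vs 1.41 at true times, truth 1.5). Marginal
fits therefore use the restricted likelihood: the root position is
integrated out under a flat prior, equivalent to keeping only between-leaf
contrasts, the standard practice for variance estimation in phylogenetic
comparative methods. The root location is then reported as its GLS
estimate (the pruning root message). One consequence: location data alone
no longer constrain the root-edge length; the sequence likelihood does.

## Sequence model

Each site evolves independently under an irreversible chain on hidden
states {0, 1..M(k), −1}: 0 → a at rate λ·π_a (π uniform by default),
any non-silent state → −1 at rate ν, with −1 absorbing; λ is the *total*
edit exit rate, split across outcomes by π. Closed forms:
P(0→0) = e^{−(λ+ν)δ}, P(0→a) = π_a e^{−νδ}(1−e^{−λδ}),
P(a→a) = e^{−νδ}, P(·→−1) = 1−e^{−νδ}; these are verified against the
matrix exponential of the generator in the tests. Observation applies
dropout: a non-silent state reads as itself with probability 1−φ and as
"?" otherwise; the silent state always reads "?". The root is unedited at
every site (no root prior). Likelihoods marginalize ancestral states by
postorder pruning with per-node rescaling (safe for thousands of cells);
an observed column with probability zero (e.g. all-"?" with φ = ν = 0)
yields −inf rather than an error. Observed "−1" entries are treated as
"?" by default — the silent state is unobservable under the dropout model
— with a strict mode that rejects them. A brute-force oracle enumerates
all ancestral assignments (≤ 7 internal nodes) and agrees with pruning to
1e-10 relative.

## Joint fitting

The joint objective is the sum of the spatial and sequence
log-likelihoods on shared branch lengths. Node times are parameterized
root-down: t_v = t_parent + (τ_end − t_parent)·sigmoid(raw_v), leaves
pinned at τ_end, making the ultrametric constraint exact and the search
space unconstrained; the zero vector is the midpoint cascade, and the map
round-trips to 1e-12 for moderate values. Positive parameters are fitted
on the log scale, φ through a logit. Optimization is L-BFGS-B with
finite-difference gradients over (raw times, log σ, angles if conditional,
log λ, log ν, logit φ), multi-restart: restart 0 starts from moment-based
values (σ from the RMS leaf spread over √τ_end; λ from the unedited
fraction; ν = φ = 0.01; times from input branch lengths when present,
otherwise the midpoint cascade; conditional-mode angles from daughter
subtree centroid directions), later restarts jitter everything with
angles drawn uniformly. Restart seeds derive from the configured seed
plus the restart index; the whole fit is deterministic given the seed,
never returns a point worse than any restart's start, and flags
non-convergence while still returning the best point. At the optimum the
fast spatial value is cross-checked against the dense computation and the
discrepancy stored on the result.

Recovery studies should pass topology-only trees: branch lengths given on
the input tree are used as the optimizer start, and starting a
sequence-only fit at the true lengths leaks truth into regions where the
likelihood is flat.

The displacement magnitude r is a fixed input, never optimized —
co-estimating r with σ is systematically unstable (each can absorb the
other's variance) — and `r_sweep` fits a user-supplied grid; on data
generated at r = 6.68 the branch-length error is U-shaped in r with its
minimum adjacent to the truth.

## Simulator

The generator mirrors the benchmark conditions: pure-birth (Yule)
topologies rescaled so leaves sit exactly at τ_end = 216 frames, N = 30
cells, σ = 1.5 (variants 0.5 and 3.0), r = 6.68, K = 10 sites with
alphabet {0, 1, 2}, λ = 0.006 per frame. Silencing ν = 0.001 and dropout
φ = 0.03 were chosen once to give moderate missingness (~19% silenced
lineages plus 3% dropout at the horizon), comparable to imaging-based
recorders; neither value is critical to the qualitative results. Division
times are snapped to the frame grid by default (SimConfig.time_resolution
= 1 frame): time-lapse recorders resolve division times to whole frames,
so true branch lengths are integers ≥ 1 — a continuous-time Yule tree
instead places some divisions within 10⁻² frames of each other, where the
relative branch-length error metric is ill-conditioned (a single
0.006-frame branch can contribute a relative error of ~280). Angles are
drawn uniformly; streams for topology, angles, locations, and sequences
are independent per seed, so changing one draw does not perturb the
others. Truth files record every latent (angles, node times, parameters)
keyed by stable node labels.

The frame simulator walks each lineage on the frame grid with Brownian
increments, applying the ±r displacement at each division; its final-frame
law matches the one-shot location simulator (two-sample KS check). With
divisions on the frame grid, the daughter–parent–daughter angle at lag 1
under r = 0 is exactly uniform on [0°, 180°] — the null of the uniformity
test; off-grid divisions would correlate the daughters through the
parent's pre-division drift and the null would hold only approximately.

What the simulator does *not* emulate: contact inhibition and crowding,
cell death, unequal division, measurement error in positions, sequencing
error in edit calls, rate heterogeneity across sites or time. Passing
recovery tests on these fixtures therefore demonstrates correctness of
the estimator under its own model class, not robustness to those
real-data effects (the sequence-model misspecification on real data is
known to degrade branch-length accuracy).

## Numerical choices

* Branch-length floor inside likelihoods: 1e-6·τ_end (relative), keeping
  the spatial covariance positive definite under zero-length branches.
* Dense quadratic forms via Cholesky solves; pruning uses per-node max
  rescaling (sequence) and exact Gaussian message passing (spatial).
* Convergence: relative log-likelihood change below 1e-6 (L-BFGS-B ftol
  set tighter by 10³); iteration cap 1000 per restart.
* Ultrametric tolerance for input validation: 1e-6 relative.
* Ties in the r-sweep argmin break toward the smallest r.
* MAPE is reported as a fraction and raises on zero-length true branches
  (the term is undefined).
* Degenerate division-angle triplets (daughter coincides with parent) are
  excluded and counted rather than propagated as NaN.

## Problem sizes

The test suite and the acceptance script use: 200 randomized trees up to
64 leaves for the spatial oracle sweep; 60 randomized trees up to 6
leaves, M ≤ 3, for the enumeration sweep; 20,000 Monte-Carlo replicates
per tree for the simulator moment checks; 30 replicates × 3 fits with 2
restarts each for the recovery study; and 25 simulated colonies of 15
cells for the angle analysis. These sizes give the statistical checks
comfortable resolution (e.g. σ̂-bias standard error ≈ 0.04) while keeping
a full run to a few minutes on one CPU.

## Known limitations

* Tree topology is fixed; no search, and no ancestral-location
  reconstruction.
* r must be supplied (or swept); no prior-based estimation.
* The marginal spatial likelihood is a second-moment Gaussian
  approximation of the circle displacement; conditional mode is exact but
  overfits the angles (see above), so per-division angle estimates are
  noisy in either mode.
* Strict molecular clock and homogeneous sites in the sequence model; no
  sequencing-error layer.
* x–y diffusion is independent and isotropic; 2D only.
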