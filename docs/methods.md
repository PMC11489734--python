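# Methods

## Scope and model

`symgate` analyses the slow conformational kinetics of Cn-symmetric
assemblies (the motivating case is a homopentameric, C5-symmetric
ligand-gated ion channel).  The pipeline is: contact featurization →
symmetry-adapted TICA (SymTICA) → k-means microstates → reversible Markov
state model → PCCA+ macrostates → kinetic observables.  Everything is
validated against an exactly solvable synthetic model, so every statistical
claim in the test suite is a comparison against a quantity obtained by dense
diagonalization, closed form, or an independent brute-force oracle.

## Feature extraction

Features are reciprocal Cα–Cα distances (nm⁻¹).  A contact is defined from
seed structures with a 1 nm cutoff; a candidate pair is included if any of
its n_fold rotated images is within the cutoff in any seed, and then its
whole orbit is included, so all symmetry blocks have equal length.  Block
*s* holds the contacts within subunit *s* plus the inter-subunit contacts at
offsets +1 and +2; for n_fold = 5 this covers every pair exactly once.  For
even n_fold, antipodal (offset n/2) pairs cannot be assigned to a unique
block and are excluded (documented limitation; all shipped analyses use odd
n_fold).

The significance filter removes contacts whose peak-to-peak/mean ratio on
raw distances falls below 0.2.  By default the ratio is computed on the
pooled series of each symmetry-equivalence class ("pooled" mode), which
makes the kept-contact mask invariant under subunit relabeling by
construction — a non-symmetric mask would break the equal-block-length
invariant.  Per-contact variants ("all": keep a class only if every image
passes; "per_contact": no closure) are available behind a flag for
sensitivity analysis.

Augmentation emits, for each trajectory, the n_fold − 1 block-rolled
pseudo-trajectories.  Block covariances averaged over block position are
mathematically identical to covariances of the explicitly augmented set, so
the SymTICA estimator never materializes the augmented data; the
equivalence is asserted to machine precision in the tests.

## SymTICA

For block-arranged features, the instantaneous and time-lagged covariance
matrices are block-circulant, built from a diagonal block and off-diagonal
blocks at each subunit offset.  Restricting the Koopman eigenproblem to the
permutation-symmetric subspace (identical eigenvector in every block)
collapses it to the b-dimensional problem on summed blocks.  We solve the
symmetric generalized eigenproblem

    Sτ ν = λ S0 ν,   S0 = Σ_o C0^(o),  Sτ = Σ_o Cτ^(o),

with Sτ symmetrized (reversibility enforced numerically), rather than
forming K = C0⁻¹Cτ: symmetric-definite solvers are better conditioned, and
the restriction to the symmetric subspace commutes with whitening, so the
result equals the summed-Koopman formulation.  Numerical conventions:

- Mean removal uses the pooled block mean (length b); after augmentation
  all block means coincide, and using the block-averaged mean makes the
  projections exactly roll-equivariant for any input.
- S0 is eigendecomposed and modes below `reg × max eigenvalue`
  (default reg = 1e-10) are discarded; the retained rank is recorded.
- Covariance pairs are taken from every frame t with t+τ in the same
  trajectory; no sliding-window weighting.
- Eigenvectors are normalized in the S0 metric and sign-fixed so the
  largest-magnitude entry is positive.
- Zero-variance features raise an error naming the offending columns.

Projections: subIC_s = νᵀ(x_s − mean) per block; ICs are the exact sums of
subICs over blocks.  ICs are invariant and subICs equivariant under block
rolls to machine precision (asserted at 1e-10).

The number of components retained downstream is a user choice (default:
the components that separate the states of interest; the toy model has one
such component).  A Gaussianity screen for discarding fast components is
deliberately not automated; the eigenvalue spectrum and per-component
distributions are exposed instead.

## Markov state model stack

- **Microstates**: scikit-learn k-means with k-means++ initialization and a
  fixed seed (deterministic).
- **Estimation**: sliding-window counts at the chosen lag, restriction to
  the largest strongly connected set (ties broken by total counts), then
  the standard detailed-balance fixed-point iteration for the reversible
  maximum-likelihood transition matrix (tolerance 1e-12 on the edge
  weights, capped sweeps, convergence failure raises with the residual).
- **Validation**: implied timescales over a lag ladder (undefined
  timescales from non-positive eigenvalues are reported as NaN flags, not
  exceptions) and a Chapman–Kolmogorov test comparing T(τ)^k set-stay
  probabilities against models re-estimated at lag kτ with the same
  estimator (so k = 1 is an identity); error bars come from Dirichlet
  posterior samples of the re-estimated matrix.
- **VAMP-2**: scores are computed from one-hot covariances of the discrete
  process; cross-validation estimates singular functions on training folds
  and scores them on held-out folds.  The no-CV variant is exact on count
  matrices and reproduces closed forms (1 + λ₂² for a perfectly
  discretized two-state chain).
- **PCCA+**: memberships from the top-m right eigenvectors via the
  inner-simplex vertex search, followed by a feasibility projection
  (clipping negative memberships and renormalizing rows) instead of the
  full simplex-rotation optimization; for the metastable systems this
  package targets the two coincide in the crisp assignment.  Non-reversible
  input is rejected with advice to estimate reversibly.
- **Macrostate populations**: crisp (argmax) aggregation of π by default;
  membership-weighted aggregation is an option.
- **Free energies**: ΔG_i = −k_B T ln Π_i with k_B T = 0.59616 kcal/mol at
  300 K, referenced to the most populated state (min ΔG = 0); zero
  populations give +inf sentinels.
- **MFPT**: the linear system m = τ1 + Tm with m = 0 on the target,
  π-weighted over the source set; unreachable targets raise.
- **Bayesian uncertainty**: reversible sampling uses Metropolis moves on
  the symmetric edge weights with log-normal multiplicative proposals
  (burn-in 50 sweeps, thinning 5 by default) initialized at the MLE; the
  non-reversible fallback draws independent Dirichlet rows with the counts
  as concentration parameters (its conjugacy is the test oracle).
- **Open bursts**: a long chain is simulated from T, projected to
  macrostates, and maximal open runs are extracted; interruptions of at
  most `merge_gap` steps (default 0) are absorbed, and a merged burst spans
  first to last open step inclusive.  This merge semantics is an explicit
  package choice.

## Symmetry analysis

The distance between two subIC tuples is the minimum Euclidean distance
over all cyclic rolls of one tuple — a pseudometric whose identity of
indiscernibles fails exactly on roll-equivalent pairs.  Symmetry-aware MDS
double-centers the squared distance matrix and clamps negative Gram
eigenvalues to zero (the metric need not be Euclidean); beyond 5000 samples
a seeded landmark subset is embedded exactly and the rest placed by
Nyström triangulation.  The inter-subunit coupling statistic is the mean
pairwise Pearson correlation over all unordered subunit pairs of one
component's per-subunit time series; the full pair matrix is returned so
alternative summaries can be formed, and pairs with constant series are
flagged NaN.

## Structural observables

Symmetry-corrected alignment computes the Kabsch RMSD for each cyclic
subunit relabeling and returns the minimizing permutation, rotation and
RMSD; only cyclic permutations are searched (Cn symmetry; mirror operations
excluded).  Pore-polygon metrics report consecutive-vertex edge lengths and
the regularity score (max−min)/mean.  Cylinder occupancy counts use a ±2 Å
default axial half-height; the hydration-cylinder radius has no privileged
default physical value and must be given explicitly in the CLI.  The pore
axis defaults to z through the centroid and is configurable.  Cylindrical
densities report raw counts and shell-volume-normalized values plus the
number of dropped points.  Reweighted histograms weight each frame by
π(state)/count(state), excluding (and counting) frames outside the MSM
active set; total mass is normalized to 1.

## Synthetic ground truth

Each of n_fold subunits is a two-state (C/O) unit.  One uniformly chosen
subunit attempts a flip per step, with probability p_CO or p_OC multiplied
by (1+g) per discordant nearest neighbour (clipped at 0.49 with a warning).
This random-scan construction keeps the exact 2^n-state chain
row-stochastic for any coupling and reversible (its stationary law is a
product measure times (1+g)^(−#discordant bonds)), and it is permutation
equivariant: P T Pᵀ = T exactly.  Under g = 0 the chain factorizes over
sites; because the random-scan kernel is the site average of per-site
kernels, its eigenvalues are *means* over sites of the per-site eigenvalues
{1, 1−(p_CO+p_OC)} — the slowest nontrivial eigenvalue is
1 − (p_CO+p_OC)/n_fold — which the tests cross-check by direct
diagonalization.

Defaults emulate a sparsely opening channel: n_fold = 5, p_CO = 0.02,
p_OC = 0.18 (per-subunit open probability 0.1, exact all-closed probability
0.9⁵ = 0.59049), step 1 ns, b = 32 features per block (a desk-scale stand-in
for the hundreds of significant contacts per block in a real receptor), and
Gaussian emissions with deterministic mean patterns whose per-feature RMS
contrast-to-noise ratio is exactly 2 (RMS|μ_O − μ_C| = 0.5, σ = 0.25).
Per-block noise is independent across blocks by default (equivariant in
distribution); `shared_noise=True` reuses one draw per frame for exact
roll equivariance.  What the generator does *not* emulate: continuous
conformational heterogeneity within states, correlated/structured noise,
state-dependent noise amplitudes, and anharmonic feature distributions —
so passing recovery tests demonstrates correctness of the estimators under
the model's assumptions, not robustness to every pathology of real MD data.

## Recovery study conditions

The end-to-end recovery runs (test suite and acceptance script) use 10⁶
frames split over 8 equilibrium-started trajectories, for uncoupled (g = 0)
and coupled (g = 0.5) subunits; SymTICA at lag 5; 100 k-means microstates
on the one state-separating IC; reversible MSM at lag 30, which sits in
the flat region of the implied-timescale curve for both conditions.  The
recovered all-closed stationary probability is measured with the package's
stationary-reweighting machinery: each subunit's C/O state is read off its
subIC (the per-subunit separation is ~11 noise standard deviations, so
per-frame classification is essentially exact), and all-closed frames are
weighted by π(microstate)/count(microstate).  The comparison yardstick is
the exact-model Monte-Carlo standard error of the occupancy, computed with
the slowest-mode autocorrelation factor (1+λ₂)/(1−λ₂) — an upper bound on
the true integrated autocorrelation correction.  Recovered slowest implied
timescales carry an irreducible seed-to-seed scatter of roughly ±2% at this
trajectory length in the coupled condition (the slow eigenvalue there is
nearly degenerate with symmetry-hidden modes), which sits inside the 5%
recovery band but not by a wide margin.

The estimator-spread comparison fits SymTICA and conventional TICA to 20
independent 5000-frame realizations and compares the standard deviation of
the slow-mode eigenvalue.  Conventional TICA's slow mode is identified as
the eigenpair whose eigenvector has the largest permutation-symmetric
component: on un-augmented data the top TICA eigenvalue is typically an
overfit, non-symmetric artifact, and the physical mode's eigenvalue
scatters roughly an order of magnitude more than SymTICA's — the
data-efficiency gap the symmetry adaptation closes.

## Known limitations

- Cyclic (Cn) symmetry only; dihedral groups are out of scope.
- Even n_fold excludes antipodal contacts from featurization.
- PCCA+ uses the inner-simplex + feasibility projection variant; for
  systems without a clear spectral gap the m-state split (like any PCCA
  variant's) is not a stable target.
- The reversible Metropolis sampler is adequate for error bars on models
  with up to a few hundred states; it is not tuned for large-k posterior
  exploration.
- Validation reports (implied timescales, CK test) are emitted as tabular
  data (CSV/JSON); plotting is left to the user.
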