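# symgate

Symmetry-adapted kinetic modelling for Cn-symmetric protein assemblies.

Homo-oligomeric ion channels such as the α7 nicotinic acetylcholine receptor
are built from *n* identical subunits arranged with cyclic (Cn) symmetry.
Their gating dynamics — transitions between closed, open, flipped,
desensitized and intermediate states — are naturally described by Markov
state models (MSMs) built on molecular-dynamics features, but conventional
dimensionality reduction ignores the symmetry: configurations that differ
only by *which* subunit deviates are treated as distinct, sampling is wasted,
and slow-mode estimates become noisy. `symgate` implements the
symmetry-adapted workflow for this setting, for computational structural
biologists building MSMs of symmetric assemblies:

- **Block featurization** — Cα contact distances (1 nm cutoff, reciprocal
  transform, peak-to-peak/mean ≥ 0.2 significance filter) arranged into
  `n_fold` blocks so the cyclic subunit relabeling acts as a roll of whole
  blocks, plus pseudo-trajectory augmentation that multiplies sampling
  `n_fold`-fold.
- **SymTICA** — time-lagged independent component analysis restricted to the
  permutation-symmetric subspace.  For block covariances C_d (diagonal),
  C_o1, C_o2 (off-diagonal at subunit offsets 1 and 2), the n·b-dimensional
  Koopman eigenproblem collapses to the b-dimensional summed problem
  K_sum ν = λ ν with K_sum = K_d + K_o1 + K_o2 + K_o2ᵀ + K_o1ᵀ, solved here
  as the symmetric generalized problem Sτ ν = λ S0 ν on summed covariance
  blocks.  Per-subunit projections (subICs) sum exactly to global,
  roll-invariant ICs.
- **MSM stack** — k-means microstates (VAMP-2 cross-validation), reversible
  maximum-likelihood transition matrices, implied timescales,
  Chapman–Kolmogorov validation, PCCA+ macrostates, stationary free energies
  ΔG = −k_B T ln Π, mean first passage times, Bayesian posterior sampling,
  and open-burst duration analysis.
- **Symmetry analysis** — the minimum-over-cyclic-rolls distance between
  subIC tuples, symmetry-aware classical MDS, per-frame subIC deviation and
  inter-subunit coupling.
- **Structural observables** — symmetry-corrected (minimum-over-relabelings)
  Kabsch alignment, pore-polygon metrics, cylinder hydration counts,
  cylindrical densities, and MSM-stationary-reweighted histograms.
- **Synthetic ground truth** — an exactly solvable Cn-symmetric two-state
  kinetic model (dense 2^n-state chain with known stationary distribution
  and spectrum) that validates the entire pipeline end to end.

## Worked example

Recover the kinetics of a C5-symmetric toy pentamer whose subunits switch
between closed (C) and open (O) with p_CO = 0.02, p_OC = 0.18 per attempted
update (per-subunit open probability 0.1):

```python
import numpy as np
from symgate.synthetic_data import (ToyModelSpec, build_toy_transition_matrix,
                                    simulate_trajectories, emit_feature_set)
from symgate.symtica import SymTICA
from symgate.msm import (cluster_microstates, estimate_msm, pcca_coarse_grain,
                         free_energies)

spec = ToyModelSpec()  # C5 pentamer: p_CO=0.02, p_OC=0.18, 32 features/block
truth = build_toy_transition_matrix(spec)
print(f"exact pi(all-closed) = {truth.pi[0]:.5f}")
print(f"exact relaxation time t2 = {truth.t2_steps:.2f} steps")

_, labels = simulate_trajectories(truth, 100_000, n_traj=2, seed=11)
features = emit_feature_set(labels, spec, seed=12)

model = SymTICA(lag=5, n_components=2, n_fold=5).fit(features)
print("SymTICA eigenvalues:", np.round(model.eigenvalues_, 3))

ics = [p.ics[:, :1] for p in model.project(features)]
dtrajs = cluster_microstates(ics, k=50, seed=13)
msm = estimate_msm(dtrajs, lag=30)
print(f"MSM implied timescale t2 = {msm.timescales(1)[0]:.1f} steps")

macro = pcca_coarse_grain(msm, 2)
print("macrostate populations:", np.round(macro.macro_pi, 3))
print("free energies (kcal/mol):", np.round(free_energies(macro.macro_pi), 3))
```

Output:

```
exact pi(all-closed) = 0.59049
exact relaxation time t2 = 24.50 steps
SymTICA eigenvalues: [0.751 0.016]
MSM implied timescale t2 = 23.7 steps
macrostate populations: [0.083 0.917]
free energies (kcal/mol): [1.434 0.   ]
```

The exact all-closed probability is 0.9⁵ = 0.59049 and the exact relaxation
time is −1/ln(1 − (p_CO+p_OC)/5) = 24.50 steps; the MSM built purely from
noisy per-frame features recovers the timescale within a few percent at
this trajectory length.  The leading SymTICA eigenvalue (0.751) is the lag-5
autocorrelation of the slow gating mode attenuated by emission noise; the
second component carries no dynamics.  PCCA+ splits the chain into an
open-rich minority macrostate 1.43 kcal/mol above the closed-rich majority.

The same workflow is available from the shell:

```sh
symgate toy --spec toy.yaml --steps 100000 --seed 11 --out features.h5
symgate symtica-fit --features features.h5 --lag-ns 5 --k 2 --out model.h5
symgate symtica-transform --features features.h5 --model model.h5 --out proj.h5
symgate msm-build --proj proj.h5 --k 50 --lag-ns 30 --macro 2 --seed 13 \
    --out-prefix msm
symgate symmetry-report --proj proj.h5 --out-prefix sym
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter choices,
numerical conventions, and known limitations.
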