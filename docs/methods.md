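# Methods

## The model

`gnnpot` implements an invariant (symmetry-order-0) message-passing
interatomic potential.  The total energy of a configuration is a sum of
atomic energies,

    E = Σ_i [ Σ_t R_t(m_i^t) + E0(Z_i) · 1[i ∈ QM] ],

where `t` runs over message-passing layers, `m_i^t` is the per-atom message
vector of layer `t`, `R_t` is a bias-free gated readout (so `R_t(0) = 0`
exactly), and `E0(Z)` is a per-element constant fitted by least squares
before network training.  Messages are built from the filtered neighbor
graph in three stages per layer:

1. **Atomic basis.**  For each atom `i`,

       A_{i,k,lm} = Σ_{j ∈ N(i)} R_{k,l}(r_ij) · Y_lm(r̂_ij) · h_{j,k},

   where `h` are per-atom channel scalars (initialised from a learned
   element embedding), `Y_lm` are orthonormal real spherical harmonics up to
   `l_max` (standard real convention, no Condon–Shortley phase), and
   `R_{k,l}(r)` is a learned radial function: the Bessel basis
   `e_n(r) = √(2/r_c)·sin(nπr/r_c)/r`, weighted by the cutoff envelope, is
   passed through a SiLU perceptron and the output is multiplied by the
   envelope once more.  The outer envelope factor is deliberate: a
   perceptron maps the zero vector to a non-zero constant, so without it an
   edge would contribute a finite energy at `r = r_c` and the potential
   energy surface would jump as neighbors cross the cutoff.  With it, every
   edge term and its first derivative vanish at `r_c` (the order-5
   polynomial envelope has two vanishing derivatives there), which is what
   the cutoff-crossing continuity test measures.

2. **Invariant products.**  Per-atom rotation invariants up to the
   configured correlation order: the `l = 0` channel of `A` (order 1), the
   power spectrum `p_{i,k,l} = Σ_m A²` (order 2), and the bispectrum

       b_{i,k,(l1,l2,l3)} = Σ_{m1 m2 m3} G^{l1 l2 l3}_{m1 m2 m3}
                            A_{i,k,l1 m1} A_{i,k,l2 m2} A_{i,k,l3 m3}

   over triangle-allowed, parity-even triples `l1 ≤ l2 ≤ l3 ≤ l_max`
   (order 3).  The couplings `G` are **real Gaunt coefficients** —
   Wigner-3j couplings transformed to the real spherical-harmonic basis —
   evaluated symbolically once per `l_max` and cached.  Because `G` is an
   isotropic tensor in the real representation, the contraction is exactly
   rotation invariant; the test suite checks this to 1e-8 under random
   rotations and cross-checks `G` against direct Gauss–Legendre quadrature
   of ∫ Y·Y·Y dΩ.

3. **Update and readout.**  `m_i = B_i · W` (a linear map of the
   concatenated invariants), `h ← h + m` (residual update), and the layer's
   energy readout is `silu(m·V)·v` with no bias terms.

Forces are exact reverse-mode derivatives, `F = −∂E/∂r`, computed by the
package's own tape-based autodiff engine (`gnnpot.autodiff`).  The engine's
backward rules are written in terms of its own primitives, so gradients can
be differentiated again — required because the training loss contains force
residuals, making the parameter gradient a second derivative.  For periodic
systems differentiation runs through displacement vectors at fixed integer
image shifts.

### QM/MM range correction

The potential is usable as a range-corrected Δ-correction in QM/MM
simulations.  Two rules implement this:

* the neighbor graph **excludes every MM–MM edge**, and
* the **per-element bias is zeroed for MM atoms**.

MM atoms still carry learned atomic energies computed from their QM-only
neighborhoods (the literal reading of the zero-bias rule); only the constant
offset is suppressed.  Consequences, all asserted by tests: an MM-only
system has exactly zero energy; an MM atom farther than the cutoff from
every QM atom contributes exactly zero even when it is close to other MM
atoms; and the energy is C¹-continuous as an MM atom crosses the cutoff.
To make the "exactly zero" guarantees bitwise (not merely to rounding),
per-atom contractions use a row-independent matrix kernel rather than a
blocked BLAS call, so appending atoms with zero features cannot perturb the
last bits of other atoms' energies.

One modelling question is genuinely open in this design: whether MM atoms
should contribute learned atomic energies at all, or only modify QM atoms'
environments.  We adopt the former (zero *bias* only); the two choices
coincide for all the invariants above except the value of near-boundary MM
atomic energies, which the training data determines either way.

### Δ-learning

Δ-learning is a data-preparation convention, not a separate code path: the
trainer sees ordinary labelled frames.  `delta_targets` subtracts a base
potential's energies and forces from reference labels (ΔE* = E_ref −
E_base); `combined_potential` adds the trained correction back
(E = E_base + ΔE_MLP) and itself satisfies the base-potential contract, so
corrections compose.  The base is a pluggable callable; bundled bases are
analytic (shifted Lennard-Jones, harmonic bonds, a Gaussian pair term).  An
external semiempirical or ab initio driver can be adapted by wrapping a
subprocess that maps an extended-XYZ file to energy (eV) and forces (eV/Å);
no such driver is required by any test.

## Presets

* `invariant_mace_s` — the large preset: 256 channels, spherical harmonics
  to order 3, correlation order 3, 2 message layers, 6 Å cutoff, 8 Bessel
  functions, order-5 polynomial envelope, radial perceptron 3×64 (SiLU; the
  activation is our choice), FP32 parameters by default.
* `invariant_small` — the desk-scale preset used by the experiments and the
  test suite: 8 channels, `l_max` 2, correlation order 3, one message
  layer, radial perceptron 2×32, FP64.  Chosen so a 20k-step training run
  completes in minutes on one CPU while remaining a faithful (if narrow)
  instance of the same architecture.

A registry maps preset names to constructors; third-party architectures can
be registered under new names and then trained, serialized and evaluated
through the same interfaces.

## Training protocol

Adam (β = 0.9/0.999), learning rate decaying geometrically from 1e-3 to
3.51e-8 over the step budget (default 1e6; the scaled-down experiments use
20k and state so).  Loss per frame:

    L = w_E (ΔE/N)² + w_F · (1/3N) Σ |ΔF|²,

averaged over the batch, with the weights tied linearly to the learning
rate so that `w_E` ramps 1 → 20 eV⁻² and `w_F` anneals 100 → 1 eV⁻²Å² over
training.  Three conventions here are ours, documented because the
protocol's published form leaves them open: the exact functional form of
the loss (per-atom-normalised energy term, per-component force term), the
shape of the weight schedule between its printed endpoints (linear in the
learning rate), and the decay granularity (continuous per step rather than
a staircase).  Batch size is ⌈256/N⌉ for frames of N atoms; datasets are
bucketed by atom count, a uniformly drawn frame selects the bucket, and the
batch is sampled from that bucket with replacement.  The per-element bias
is fitted once by least squares (QM atoms only) and frozen during Adam.

Training is bitwise reproducible in FP64 for a fixed seed.  FP32 is the
default parameter precision of the large preset; finite-difference force
validation requires FP64, which the tests use throughout.

## Evaluation

Energy MAE/RMSE are computed over per-frame **total** energies and reported
in kcal/mol (1 eV = 23.060548 kcal/mol); force MAE/RMSE over all 3N
components in kcal/(mol·Å).  Totals (rather than per-atom energies) match
the customary table format in this area; a per-atom option exists.  The
query-by-committee deviation is the maximum over atoms of the standard
deviation of the force vector across an ensemble (component-wise variance
summed, square-rooted) — the standard exploration criterion for
active-learning workflows; only the statistic is provided, not the
surrounding workflow.

## Synthetic data

The generators produce the statistical structure the method assumes, with
exact labels (force = −∇E analytically; verified by finite differences):

* `lj_cluster` — argon-like clusters (ε = 0.0104 eV, σ = 3.4 Å, LJ shifted
  to zero at 10 Å).  Atoms are packed sequentially at a minimum separation
  of 0.8σ, locally relaxed on the LJ surface, then jittered with Gaussian
  displacements of 0.15 Å — configurations around minima, the regime a
  trained potential is meant to interpolate.
* `perturbed_pair` — the same geometries labelled by LJ plus a smooth
  Gaussian pair term A·exp(−r²/2λ²) (defaults A = 0.02 eV, λ = 1.5 Å,
  kept ≤ r_c/3 so the residual is genuinely short-ranged).  The base is
  returned alongside, so the true Δ has a closed form.
* `qmmm_scene` — QM cores with MM shells straddling the cutoff, plus a
  radial family that walks one MM atom across `r_c` for the continuity
  probe.

What these toys do **not** emulate: chemical diversity (one element, no
charges), conformational sampling from dynamics, label noise, and many-body
reference physics beyond pair terms.  Passing the scaled-down experiments
therefore demonstrates that the machinery — graph construction, features,
autodiff, the training protocol, Δ-composition — is correct and convergent,
not that the architecture reaches any particular accuracy on real chemistry.

## Scaled-down experiments

* **Convergence** (`gnnpot.experiments.lj_convergence`): 500 LJ frames of
  8 atoms, 19:1 train/test split, `invariant_small`, 20k steps, FP64.
  Passing bar: test force MAE below 20 % of the label force RMS.  Typical
  result: ≈ 10 % at 2k steps and well under that by 20k.
* **Δ-advantage** (`gnnpot.experiments.delta_advantage`): perturbed-pair
  family, 200 frames, equal 1500-step budgets for the ΔMLP (trained on
  ΔE*, ΔF*, evaluated as base + correction) and the pure MLP (trained on
  the reference directly).  The Δ route wins by orders of magnitude on this
  family because the correction is small and smooth while the raw reference
  contains the stiff LJ core — the mechanism the Δ formulation exploits.

## Numerical choices and edge cases

* Strict inequality `r < r_c` at the cutoff; ties excluded (the envelope is
  zero there, so the choice only affects determinism, not values).
* All periodic images within the cutoff are enumerated (no minimum-image
  assumption); cells smaller than 2·r_c, including self-images, are handled.
* Parameter initialisation: uniform fan-in scaling, seeded; two models with
  the same spec and seed are bitwise identical.
* Degenerate inputs: overlapping atoms (r < 1e-6 Å) are rejected by the
  analytic bases; non-finite model outputs raise instead of propagating;
  an empty (fully filtered) graph yields bias-only energies.
* Serialization: `.gpt` zip archive with a versioned JSON header, raw
  little-endian parameter blobs and a SHA-256 manifest; loading verifies
  checksums (tamper ⇒ error) and the format version.  Save → load is
  bitwise on the same hardware and precision.

## Known limitations

* Invariant messages only (symmetry order 0); equivariant (l ≥ 1) message
  passing is out of scope, though the registry accepts richer models.
* No virial/stress, no long-range electrostatics, no charge or spin inputs
  — the model sees only coordinates and elements.
* `l_max ≤ 3`; higher orders would need an extended harmonic table.
* Energy labels are treated as opaque totals; no atomization-energy
  convention is imposed.
* CPU-only; the engine is written for correctness and desk-scale problem
  sizes, not throughput.
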