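# Methods

This note documents the models and numerical procedures implemented in
`tnep`, the design choices made where the design was genuinely open, and
what the synthetic experiments do and do not demonstrate.

## The tensorial site-quantity model

The package extends the neuroevolution-potential (NEP) family of
machine-learned interatomic models from scalar site energies to rank-1 and
rank-2 tensors. Every atom `i` carries a scalar site quantity

    U_i = net(q_i),

where `net` is a single-hidden-layer perceptron (tanh activation, linear
output with bias) and `q_i` is an invariant descriptor of the atom's
neighborhood (below). The physical dimension of `U_i` follows the model
kind: charge for dipole models, polarizability for rank-2 models.

The building block for tensors is the *partial force* ∂U_i/∂r_ij — the
gradient of atom i's site quantity with respect to its displacement vector
r_ij = r_j − r_i to neighbor j — and the virial-form pair tensor

    W^{uv} = Σ_i Σ_{j≠i} r_ij^u ∂U_i/∂r_ij^v.

Predictions are assembled as

* dipole (rank 1):  μ^v = Σ_i Σ_{j≠i} d_ij² ∂U_i/∂r_ij^v — the virial-form
  tensor contracted with r_ij over its **first** index (the distance squared
  d_ij² = r_ij·r_ij appears explicitly). The alternative second-index
  contraction satisfies the same symmetry laws; the convention used is
  recorded in the model file header and switchable.
* polarizability / susceptibility (rank 2):
  α^{uv} = δ^{uv} Σ_i U'_i + ½(W + Wᵀ)^{uv}.

Because every term depends on interatomic displacement vectors only, the
predictions are exactly translation invariant, transform as a vector
(rank 1) or by conjugation (rank 2) under rotations, and are invariant
under permutations of same-species atoms. The explicit symmetrization
(W + Wᵀ)/2 is applied because reference α/χ tensors are symmetric and an
antisymmetric residual would be unlearnable noise in the loss.

### Two network heads for rank-2 models

Rank-2 models use **two independent networks of identical shape**: the
*pair head*, whose gradients enter W, and the *scalar head* U', whose
per-atom values feed the isotropic δ-term. With a single shared network
the δ-term ties the network's values to the very weights whose gradients
shape the anisotropy; on the bond-polarizability benchmark below this
over-constraint produces a hard accuracy floor (≈12.5% diagonal RRMSE that
neither longer training, more neurons, nor richer descriptors move, and
that a linear surrogate reproduces exactly), while the two-head form fits
the same data to well under 1%. Published TNEP polarizability model files
likewise carry twice the network parameters of a dipole model. Dipole
models have a single head — the rank-1 expression contains no value term.

### Units

Positions and cutoffs are Angstrom, dipoles e·bohr, polarizabilities
bohr³, susceptibilities unitless. Labels are carried as-is and never
rescaled implicitly; `tnep.units` exposes the bohr↔Å factor
(1 bohr = 0.529177210903 Å) for callers. Susceptibility models put no
volume convention inside the model — per-molecule or per-volume
normalization is a data-side decision (the `per_atom_normalized` loss
option divides predictions and labels by the atom count for extensive
targets).

## Descriptor

The atom-centered descriptor is deliberately simple but satisfies every
contract the tensor machinery needs (smoothness, C¹ cutoff behavior,
invariance, analytic pair gradients):

* radial channels, n = 0..n_max^R:
  q^R_{i,n} = Σ_j w_n(s_i,s_j) g_n(d_ij),
  with g_n(d) = T_n(2d/r_cut − 1) f_c(d), Chebyshev polynomials damped by
  the smooth cutoff f_c(d) = ½[1 + cos(π d/r_cut)];
* angular channels, n = 0..n_max^A, l = 1..l_max:
  q^A_{i,n,l} = Σ_{j≠k} w̃_n(s_i,s_j) w̃_n(s_i,s_k) g_n(d_ij) g_n(d_ik)
  P_l(cos θ_jik), with Legendre polynomials P_l and the (smaller) angular
  cutoff.

The descriptor length is (n_max^R + 1) + (n_max^A + 1)·l_max. The
species-pair mixing weights w_n are trainable and **per basis channel**
(shared across l for the angular block): a single scalar weight per
species pair turned out to be too coarse — it leaves the radial gradient
profile of unlike pairs locked together and demonstrably caps rank-2
accuracy — while per-channel weights mirror the species-resolved expansion
coefficients of full NEP descriptors at a fraction of the complexity. All
weights default to 1, so species are undistinguished until training moves
them.

Pair gradients ∂q_i/∂r_ij are analytic (Chebyshev/Legendre recurrences for
values and derivatives) and are validated against central finite
differences (step 1e-5 Å, relative error < 1e-6) in the test suite.

Optional per-channel standardization (z-scoring against the training set)
is available and stored in the model file; it is **off by default** — on
the benchmarks here it did not help the optimizer and slightly slowed
convergence, but the hook is kept because evolution strategies are
scale-sensitive in general.

## Neighbor enumeration

Periodic neighbors come from explicit image replication: the number of
image shells per lattice direction is ceil(cutoff / plane distance), so
skewed cells are handled without minimum-image rounding errors. A neighbor
appears once per image; self pairs arise only through nonzero images.
Pairs use strict d < cutoff (a tie at the cutoff contributes zero anyway
through f_c). The table is validated against brute-force 27-image
enumeration on random cells.

## Training

The loss is

    L(z) = Δ(z) + λ₁·mean(|z|) + λ₂·sqrt(mean(z²)),

with Δ the component-wise RMSE of the predicted tensors over the training
set — 3 components for dipoles, the 6 independent components of each
symmetric tensor for rank 2 (off-diagonals counted once) — and optional
per-structure weights. The regularization means run over all trainable
parameters, making λ values comparable across model sizes.

The optimizer is the separable natural evolution strategy (SNES, Schaul
et al. 2011): per-dimension Gaussian mean and step size, symmetric
(antithetic) sampling, rank-based utility shaping, default population
4 + ⌊3 ln d⌋ rounded up to even, learning rates η_μ = 1 and
η_σ = (3 + ln d)/(5√d). Identical seeds give bit-identical runs. For
harder fits the examples and acceptance experiments restart SNES a few
times and keep the best training loss — the standard guard against an
unlucky initial population. A NaN objective aborts with a diagnostic.

Metrics: RMSE in model units; RRMSE = RMSE / std(reference components);
R² = 1 − SS_res/SS_tot (a constant predictor at the reference mean scores
exactly 0). Rank-2 fits additionally report diagonal / off-diagonal
splits, which separate the isotropic from the anisotropic response.

`shuffle_split` implements the protocol used for learning-curve studies:
a fixed holdout drawn first, then training sets sampled (with replacement
by default) from the remaining pool, several repeats per size, all seeded.

## Synthetic ground truths

Three generators make every part of the pipeline testable without
external data; all are seeded and all labels obey the same symmetry laws
the models must obey, so generator bugs cannot masquerade as model bugs.

* **Point-charge dipoles**: displaced copies of a rigid template (default:
  water, r_OH = 0.9572 Å, HOH 104.52°) labeled with μ = Σ Q_i r_i in
  e·bohr (TIP3P-style charges −0.834/+0.417 e by default). For templates
  with net charge the relative dipole about the center of mass is used, so
  labels are always translation invariant. Displacements are uniform in a
  cube (±0.1 Å by default) to bound geometry distortion.
* **Bond polarizability**: α = Σ_bonds [a_∥ r̂r̂ᵀ + a_⊥(I − r̂r̂ᵀ)] in bohr³
  over a fixed bond list or a distance rule (defaults a_∥ = 2, a_⊥ = 1,
  the two O–H bonds of the water template). An optional (d₀/d)^p distance
  scaling exists but is off by default. Note a constant-coefficient bond
  model on a fixed bond topology has *exactly constant trace*, so the
  whole diagonal signal is anisotropic — a deliberately unforgiving target
  for the isotropic/anisotropic split of the rank-2 model.
* **Harmonic tensor trajectories**: sums of cosines at stated wavenumbers
  per tensor channel (including a pure-γ "iso" channel), the analytic
  oracle for the spectra code. Wavenumbers at or above the Nyquist limit
  of the time step are rejected.

What these data do **not** emulate: thermal (Boltzmann) sampling,
anharmonic mode coupling, polarization/charge-transfer effects beyond
fixed charges and rigid bond response, periodic-boundary electrostatics,
and label noise at DFT magnitudes. Passing the recovery experiments shows
the pipeline can find a representable ground truth from realistic-scale
geometry variation — it does not certify accuracy on ab initio data.

## Spectra

The autocorrelation function (ACF) is averaged over time origins with the
unbiased 1/(N−τ) normalization, computed by FFT. Line shapes are cosine
transforms of the windowed ACF (the ACF is even), reported on ω ≥ 0 with
the grid k/(n_fft·dt) converted via 1 fs⁻¹ = 33356.40952 cm⁻¹. Defaults:
Hann window over lags, zero-padding factor 4, mean subtraction on, max lag
half the series — all switchable for convention comparisons. A
Wiener–Khinchin consistency test checks the transform of the (biased,
unwindowed) ACF against the zero-padded periodogram to 1e-8 relative.

IR: the line shape M(ω) is one third of the trace of the dipole ACF
transform. The classical absorption prefactor — first-order expansion of
the Boltzmann factor — is fixed to β ω² M(ω)/(6 c n) with ω in rad/fs,
β = 1/(k_B T) in eV⁻¹ and c in Å/fs; the scale is arbitrary but
reproducible, and band-normalized comparisons are unaffected. The ω = 0
bin is exactly zero in this mode.

Raman (Stokes, ion-clamped static susceptibility for extended systems):
with α = γI + β (γ = Tr α/3, β traceless), the channels are
iso = transform⟨γ(0)γ(t)⟩, aniso = (2/15)·transform⟨Tr β(0)β(t)⟩,
polarization pairs ⟨α_ab(0)α_ab(t)⟩ for Cartesian axes a,b (the Porto
combinations Z(XX)Z̄ ↔ xx, Z(XY)Z̄ ↔ xy), and
full = transform⟨Tr α(0)α(t)⟩, which satisfies full = 3·iso + (15/2)·aniso
identically per frame pair because Tr β = 0 kills the cross terms; the
identity survives the estimator because ACF and transform are linear.
No quantum correction factors are applied anywhere.

`normalize_by_band` divides each channel by its trapezoidal integral over
a stated band (grid points inside the band), making band-normalized
comparisons idempotent.

## Problem sizes and experiment design

The recovery experiments are sized for a desk-class single-CPU run:

* teacher–student: 200 train / 200 validation three-atom structures, a
  4-neuron teacher, four SNES restarts of 5000 generations
  (single-species systems disable the mixing block, which is a pure
  redundancy there);
* point-charge dipole: 300/300 water molecules, 10 neurons, 2000
  generations;
* bond polarizability: 300/300 water molecules, 12 neurons per head, 4000
  generations, λ₁ = λ₂ = 1e-4 (the tensor components are of order 1 bohr³,
  so a heavier regularization would dominate the fit).

Under these conditions the validation RRMSEs land well inside the target
bands (teacher–student below 1%, point-charge dipole below 2%,
bond-polarizability diagonal below 5% and off-diagonal below 10%), with
SNES convergence — not model capacity — the binding constraint.

## Known limitations

* The descriptor is a compact stand-in for the full NEP basis (no
  4-body/higher channels, no message passing); it is contract-compatible,
  not numerically identical, so published NEP/TNEP model files cannot be
  loaded.
* Only the tensor models are trainable — potential-energy-surface models
  and MD are out of scope; trajectories are inputs.
* SNES is the only optimizer, as in the NEP lineage; gradient-based
  training is deliberately absent.
* The classical IR prefactor and the (1, 2/15) iso/aniso coefficients fix
  one common convention; absolute intensities are arbitrary-scale, and
  users comparing against other codes should band-normalize.
* ACF estimation assumes uniformly sampled, stationary series; there is no
  resampling and no nonuniform-time support.
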