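# tnep

Machine-learned **rank-1 and rank-2 tensorial properties** of molecules and
materials — dipole moments **μ**, molecular polarizabilities **α**, and
electric susceptibilities **χ** — in the neuroevolution-potential (NEP)
style, together with the correlation-function pipeline that turns predicted
tensor time series into **infrared and Raman spectra**.

The package is aimed at people who run molecular-dynamics simulations and
want vibrational spectra: train a tensor model on labeled configurations,
evaluate it along a trajectory, Fourier-transform the autocorrelation
functions, and read off the spectrum.

## The model

Every atom *i* carries a scalar site quantity `U_i = net(q_i)`, a
single-hidden-layer perceptron applied to an invariant descriptor `q_i` of
the atomic environment (Chebyshev radial channels, Legendre angular
channels, trainable species-pair weights). Tensors are built from the
*partial forces* ∂U_i/∂**r**_ij and the virial-form pair tensor
W^{uv} = Σ_ij r_ij^u ∂U_i/∂r_ij^v:

* **dipole** (rank 1): μ^v = Σ_i Σ_j d_ij² ∂U_i/∂r_ij^v (units e·bohr),
* **polarizability / susceptibility** (rank 2):
  α^{uv} = δ^{uv} Σ_i U′_i + ½(W + Wᵀ)^{uv} (bohr³ / unitless),
  with an independent second network head U′ for the isotropic term.

These forms are exactly translation invariant, rotationally equivariant
(vector law for μ, conjugation law for α), and invariant under same-species
permutations — properties the test suite checks to 1e-9 against random
rigid motions and naive brute-force reimplementations.

Training minimizes component-wise RMSE plus L1/L2 regularization with the
**separable natural evolution strategy** (SNES) — derivative-free,
per-dimension step sizes, bit-reproducible for a fixed seed.

Spectra: the IR line shape is the cosine transform of the dipole ACF
(⅓ of its trace), optionally weighted by the classical βω² prefactor; Raman
channels come from the decomposition α = γI + β into isotropic (polarized)
⟨γγ⟩ and anisotropic (depolarized) (2/15)⟨Tr ββ⟩ parts, plus Cartesian
polarization pairs (Porto combinations like Z(XX)Z̄ ↔ `xx`). No quantum
correction factors are applied. See `docs/methods.md` for conventions,
defaults and limitations.

## Worked example

Train a dipole model on a synthetic point-charge water dataset
(`python examples/01_train_dipole_model.py`):

```
gen     0  loss 0.12195  train RRMSE 26.94%
gen   200  loss 0.04806  train RRMSE 9.95%
gen   400  loss 0.02263  train RRMSE 3.81%
gen   600  loss 0.01384  train RRMSE 1.67%

validation: RMSE 0.0084 e*bohr  RRMSE 1.86%  R^2 0.9997
```

300 displaced water molecules are labeled with their exact point-charge
dipole (TIP3P-style charges); after 800 SNES generations the model predicts
held-out dipoles to 1.9% of their standard deviation (R² ≈ 1), i.e. it has
recovered the ground-truth charge model from geometry alone. Longer runs
push this well under 1%.

Spectra from a dipole trajectory with modes at 600 and 1650 cm⁻¹
(`python examples/03_ir_spectrum.py`):

```
band  400- 800 cm^-1: peak at   599.6 cm^-1, fractional area 0.269
band 1400-1900 cm^-1: peak at  1650.1 cm^-1, fractional area 0.731
```

Peaks land on the driving frequencies to within one grid bin; the classical
ω² prefactor boosts the stiff mode. `examples/02_polarizability_model.py`
and `examples/04_raman_channels.py` do the same for rank-2 models and the
Raman channel decomposition (including the exact identity
full = 3·iso + (15/2)·aniso).

## Command line

A thin CLI wraps the library for shell workflows:

```sh
tnep synth --kind point_charge --count 300 -o train.xyz
tnep train train.cfg                      # key=value config
tnep predict model.txt frames.xyz -o mu.tsv
tnep spectrum traj.dat --kind ir --temperature 300 -o ir.tsv
```

Structures are extended XYZ with per-structure labels in the comment line
(`dipole="dx dy dz"`, `pol="a11 ... a33"`); trajectories are columnar text
(time then 3 or 9 values) or labeled extended-XYZ frame sequences; models
are versioned plain text. Identical config + seed reproduce outputs
byte-for-byte.

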