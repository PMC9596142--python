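# vibroraman

Nonadiabatic vibrational resonance Raman (vRR) and absorption spectra for
molecules described by linear vibronic coupling (LVC) models: exact
wavepacket propagation on coupled diabatic harmonic surfaces,
cross-correlation functions, time-dependent transition polarizabilities,
rotational invariants, and side-by-side comparison of three protocols
(fully coupled `lvc`, uncoupled-with-interference `vg_int`,
uncoupled-without-interference `vg_sum`), plus closed-form single-state
vertical-gradient (VG) correlation functions at the Franck-Condon level
and a numerical Herzberg-Teller route.

## Model and conventions

A model is defined in dimensionless ground-state normal coordinates:

* ground PES `V_g = sum_j omega_j q_j^2 / 2`, zero-point energy
  `E_g0 = sum_j omega_j / 2`;
* diabatic excited PES
  `V_i = E_i + sum_j (omega_j q_j^2 / 2 + lambda_ii,j q_j)`
  (same modes and frequencies as the ground state);
* interstate couplings `V_ij = sum_j lambda_ij,j q_j`;
* constant (FC) transition dipoles per diabatic state, with an optional
  dipole derivative for single-state Herzberg-Teller calculations.

Internally all energies are in eV, time in hbar/eV (1 hbar/eV
= 0.658211957 fs), hbar = 1.  Model files are JSON
(`schema_version: "1"`) storing frequencies in cm^-1
(1 eV = 8065.543937 cm^-1) and energies in eV; unknown keys are
rejected.  Wavelengths convert via `lambda[nm] * E[eV] = 1239.841984`.

The dynamics is numerically exact in a truncated harmonic product basis
(per-mode cap and total-quanta cap): dense eigendecomposition up to
dimension 4000, Krylov exponential action above.  This targets desk-scale
models (up to ~8 modes); it is not an MCTDH replacement.

The vRR intensity uses the standard complex-tensor rotational invariants
and the prefactor `omega_I * (omega_I - omega_f)^3` with a global
constant 1 — only relative intensities are meaningful.

## Command line

```sh
vibroraman fixtures --seed 1 --out models/
vibroraman validate --model models/conical_2mode_2state.json
vibroraman vrr --model models/conical_2mode_2state.json \
    --protocol lvc --gamma-ev 0.04 --excitation-nm 233 \
    --scale 0.96 --conv-hwhm-cm1 15 --out run/
vibroraman abs --model models/conical_2mode_2state.json \
    --abs-hwhm-ev 0.04 --abs-hwhm-ev 0.12 --out run_abs/
vibroraman profile --model models/conical_2mode_2state.json --mode 2 --out run_prof/
vibroraman convergence --model models/conical_2mode_2state.json --basis-ntot 8
```

Options can also come from a YAML config file (`--config`); explicit
flags override file values, which override built-in defaults.  Every run
writes plain-text TSV outputs plus a `manifest.json` recording the
resolved parameters, package version and any numerical warnings
(basis-truncation and quadrature warnings are always recorded).
`--shift-states LABEL:DELTA_EV` rigidly shifts selected state energies;
`--ht-states LABEL` switches listed states to Herzberg-Teller dipoles
(VG protocols, requires `dipole_deriv` in the model file).

## Python API

```python
import numpy as np
from vibroraman import fixtures, compute_vrr, absorption_spectrum, SpectrumSettings

model = fixtures.conical_two_state()
settings = SpectrumSettings(gamma=0.04, n_tot=10)
vrr = compute_vrr(model, "lvc", settings=settings)      # 2D map
abs_spec = absorption_spectrum(model, "lvc", hwhm=0.04, settings=settings)
```

Lower-level pieces (`enumerate_basis`, `build_hamiltonian`, `propagate`,
`cross_correlations`, `sum_over_states_alpha`,
`compose_tensor_correlation`, `half_fourier_alpha`,
`rotational_invariants`, ...) are exported from the package root; the
sum-over-states path doubles as an independent oracle for the
time-dependent route in the test suite.

## Random model generator

`random_model(nmodes, nstates, seed, ranges)` uses
`numpy.random.default_rng(seed)` (PCG64) with a fixed draw order:
mode frequencies (sorted), then per state energy, gradient and dipole,
then one coupling vector per unordered state pair in (i < j) order.
Vector components get a magnitude uniform within the configured range
and an independent random sign.  The same seed therefore reproduces
byte-identical model files across runs and platforms.

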