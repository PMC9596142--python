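"""Canonical hand-built models used by the test suite and the CLI.

All constructors are deterministic; frequencies are chosen in the
fingerprint region and displacements kept moderate so that modest
basis truncations (n_tot ~ 10) are converged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import CouplingSpec, LVCModel, ModeSpec, StateSpec, random_model
from .units import CM1_PER_EV

__all__ = [
    "displaced_one_mode",
    "three_mode_single_state",
    "conical_two_state",
    "cs_bright_dark",
    "interference_two_state",
    "write_fixture_set",
]


def displaced_one_mode(
    s_hr: float = 0.5, omega_cm1: float = 1000.0, e_v: float = 5.0,
    dipole=(1.0, 0.0, 0.0),
) -> LVCModel:
    """1 mode / 1 state displaced oscillator with Huang-Rhys ``s_hr``."""
    w = omega_cm1 / CM1_PER_EV
    lam = np.sqrt(2.0 * s_hr) * w
    return LVCModel(
        modes=(ModeSpec(index=1, omega=w, symmetry="A'"),),
        states=(
            StateSpec(
                label="S1", symmetry="A'", energy=e_v,
                gradient=np.array([lam]), dipole=np.asarray(dipole, float),
            ),
        ),
    )


def three_mode_single_state() -> LVCModel:
    """3 modes / 1 state, Huang-Rhys factors 0.4 / 0.25 / 0.1."""
    omegas_cm1 = np.array([600.0, 1100.0, 1500.0])
    s_hr = np.array([0.4, 0.25, 0.1])
    w = omegas_cm1 / CM1_PER_EV
    lam = np.sqrt(2.0 * s_hr) * w
    return LVCModel(
        modes=tuple(
            ModeSpec(index=j + 1, omega=float(w[j]), symmetry="A'") for j in range(3)
        ),
        states=(
            StateSpec(
                label="S1", symmetry="A'", energy=5.0,
                gradient=lam, dipole=np.array([0.8, 0.5, 0.0]),
            ),
        ),
    )


def conical_two_state(coupling: float = 0.08) -> LVCModel:
    """2 modes / 2 states: one tuning mode (different gradients) and one
    coupling mode carrying the single interstate coupling component."""
    w = np.array([800.0, 1200.0]) / CM1_PER_EV
    modes = (
        ModeSpec(index=1, omega=float(w[0]), symmetry="A'"),
        ModeSpec(index=2, omega=float(w[1]), symmetry="A'"),
    )
    s1 = StateSpec(
        label="S1", symmetry="A'", energy=4.8,
        gradient=np.array([0.9 * w[0], 0.0]), dipole=np.array([1.0, 0.2, 0.0]),
    )
    s2 = StateSpec(
        label="S2", symmetry="A'", energy=5.2,
        gradient=np.array([-0.7 * w[0], 0.0]), dipole=np.array([0.4, 0.8, 0.0]),
    )
    coup = CouplingSpec(bra="S1", ket="S2", lam=np.array([0.0, coupling]))
    return LVCModel(modes=modes, states=(s1, s2), couplings=(coup,))


def cs_bright_dark(coupling: float = 0.07, dark_dipole: float = 0.08) -> LVCModel:
    """Cs model: bright A' state, weak A'' state, A'' coupling mode.

    Three electronic surfaces counting the ground state.  The A'' mode
    (mode 3) carries no intrastate gradient, so at the FC level its
    fundamental is silent unless the A'-A'' coupling feeds amplitude
    into the A'' surface; its intensity is then emitted through the
    (small, out-of-plane) A'' transition dipole.
    """
    w = np.array([700.0, 1300.0, 400.0]) / CM1_PER_EV
    modes = (
        ModeSpec(index=1, omega=float(w[0]), symmetry="A'"),
        ModeSpec(index=2, omega=float(w[1]), symmetry="A'"),
        ModeSpec(index=3, omega=float(w[2]), symmetry="A''"),
    )
    bright = StateSpec(
        label="ppi", symmetry="A'", energy=5.0,
        gradient=np.array([0.8 * w[0], 0.6 * w[1], 0.0]),
        dipole=np.array([1.0, 0.3, 0.0]),  # in plane
    )
    dark = StateSpec(
        label="npi", symmetry="A''", energy=5.4,
        gradient=np.array([0.3 * w[0], -0.4 * w[1], 0.0]),
        dipole=np.array([0.0, 0.0, dark_dipole]),  # out of plane, weak
    )
    couplings = ()
    if coupling != 0.0:
        couplings = (
            CouplingSpec(bra="ppi", ket="npi", lam=np.array([0.0, 0.0, coupling])),
        )
    return LVCModel(modes=modes, states=(bright, dark), couplings=couplings)


def interference_two_state(gap: float = 0.5) -> LVCModel:
    """Two uncoupled bright states with parallel dipoles sharing one
    displaced mode (opposite displacement signs); their overlapping
    resonances interfere destructively in the valley between the bands."""
    w = 1000.0 / CM1_PER_EV
    modes = (ModeSpec(index=1, omega=w, symmetry="A'"),)
    s1 = StateSpec(
        label="S1", symmetry="A'", energy=5.0 - gap / 2.0,
        gradient=np.array([0.8 * w]), dipole=np.array([1.0, 0.0, 0.0]),
    )
    s2 = StateSpec(
        label="S2", symmetry="A'", energy=5.0 + gap / 2.0,
        gradient=np.array([-0.8 * w]), dipole=np.array([1.0, 0.0, 0.0]),
    )
    return LVCModel(modes=modes, states=(s1, s2))


def write_fixture_set(seed: int, outdir) -> list[Path]:
    """Write the canonical fixture models plus two seeded random ones."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = {
        "displaced_1mode.json": displaced_one_mode(),
        "three_mode_single_state.json": three_mode_single_state(),
        "conical_2mode_2state.json": conical_two_state(),
        "cs_bright_dark.json": cs_bright_dark(),
        "random_a.json": random_model(3, 2, seed),
        "random_b.json": random_model(2, 3, seed + 1),
    }
    paths = []
    for name, model in items.items():
        path = outdir / name
        model.save(path)
        paths.append(path)
    return paths
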