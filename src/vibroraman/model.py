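"""Linear vibronic coupling (LVC) models.

A model collects the ground-state normal modes (shared by every diabatic
surface), the excited diabatic states (vertical energy, intrastate
gradient, constant transition dipole) and the interstate coupling
gradients, one vector per unordered state pair.

Conventions (pinned; the sign of the gradients is unobservable in
single-state intensities and fixed globally for determinism):

* ground PES        V_g   = sum_j omega_j q_j^2 / 2
* diabatic PES      V_i   = E_i + sum_j (omega_j q_j^2 / 2 + lam_ii,j q_j)
* coupling          V_ij  = sum_j lam_ij,j q_j
* ground ZPE        E_g0  = sum_j omega_j / 2
* excited minimum at q_j = -lam_j / omega_j, Huang-Rhys S_j = lam_j^2 / (2 omega_j^2)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import CM1_PER_EV

SCHEMA_VERSION = "1"

__all__ = [
    "ModeSpec",
    "StateSpec",
    "CouplingSpec",
    "LVCModel",
    "RandomRanges",
    "validate_model",
    "symmetry_audit",
    "huang_rhys",
    "apply_state_shift",
    "random_model",
    "load_model",
    "save_model",
]


@dataclass(frozen=True)
class ModeSpec:
    """One ground-state normal mode; ``omega`` in eV internally."""

    index: int
    omega: float
    symmetry: str = "A'"


@dataclass(frozen=True)
class StateSpec:
    """One excited diabatic state.

    ``energy`` is the vertical energy at the ground equilibrium (eV),
    ``gradient`` the intrastate gradient lam_ii (eV per dimensionless
    coordinate, one entry per mode) and ``dipole`` the constant
    (Franck-Condon) transition dipole from the ground state.
    ``dipole_deriv`` optionally carries a (3, nmodes) Herzberg-Teller
    derivative, used only by the single-state HT machinery.
    """

    label: str
    energy: float
    gradient: np.ndarray
    dipole: np.ndarray
    symmetry: str = "A'"
    dipole_deriv: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "gradient", np.asarray(self.gradient, dtype=float))
        object.__setattr__(self, "dipole", np.asarray(self.dipole, dtype=float))
        if self.dipole_deriv is not None:
            object.__setattr__(
                self, "dipole_deriv", np.asarray(self.dipole_deriv, dtype=float)
            )


@dataclass(frozen=True)
class CouplingSpec:
    """Interstate coupling gradient lam_ij for one unordered state pair."""

    bra: str
    ket: str
    lam: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))

    @property
    def pair(self) -> frozenset:
        return frozenset((self.bra, self.ket))


@dataclass(frozen=True)
class LVCModel:
    modes: tuple[ModeSpec, ...]
    states: tuple[StateSpec, ...]
    couplings: tuple[CouplingSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "modes", tuple(self.modes))
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "couplings", tuple(self.couplings))

    # -- derived views -------------------------------------------------
    @property
    def nmodes(self) -> int:
        return len(self.modes)

    @property
    def nstates(self) -> int:
        return len(self.states)

    @property
    def omegas(self) -> np.ndarray:
        """Mode frequencies in eV, ordered by mode index."""
        return np.array([m.omega for m in self.modes], dtype=float)

    @property
    def zpe(self) -> float:
        """Ground-state zero-point energy E_g0 = sum omega/2 (recomputed)."""
        return 0.5 * float(np.sum(self.omegas))

    @property
    def state_labels(self) -> list[str]:
        return [s.label for s in self.states]

    def state(self, label: str) -> StateSpec:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"unknown state label {label!r}; have {self.state_labels}")

    def state_index(self, label: str) -> int:
        for i, s in enumerate(self.states):
            if s.label == label:
                return i
        raise KeyError(f"unknown state label {label!r}; have {self.state_labels}")

    def dipole_matrix(self) -> np.ndarray:
        """(nstates, 3) array of transition dipoles."""
        return np.array([s.dipole for s in self.states], dtype=float)

    def coupling_matrix(self) -> np.ndarray:
        """(nstates, nstates, nmodes) symmetric array of lam_ij vectors."""
        lam = np.zeros((self.nstates, self.nstates, self.nmodes))
        for c in self.couplings:
            i, j = self.state_index(c.bra), self.state_index(c.ket)
            lam[i, j] = c.lam
            lam[j, i] = c.lam
        return lam

    def with_couplings_zeroed(self) -> "LVCModel":
        return replace(self, couplings=())

    def single_state(self, label: str) -> "LVCModel":
        """Sub-model containing one excited state and no couplings."""
        return LVCModel(modes=self.modes, states=(self.state(label),), couplings=())

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "units": {"omega": "cm-1", "energy": "eV"},
            "modes": [
                {
                    "index": m.index,
                    "omega_cm1": m.omega * CM1_PER_EV,
                    "symmetry": m.symmetry,
                }
                for m in self.modes
            ],
            "states": [],
            "couplings": [
                {"bra": c.bra, "ket": c.ket, "lambda_ev": c.lam.tolist()}
                for c in self.couplings
            ],
        }
        for s in self.states:
            entry = {
                "label": s.label,
                "symmetry": s.symmetry,
                "energy_ev": s.energy,
                "gradient_ev": s.gradient.tolist(),
                "dipole": s.dipole.tolist(),
            }
            if s.dipole_deriv is not None:
                entry["dipole_deriv"] = s.dipole_deriv.tolist()
            d["states"].append(entry)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LVCModel":
        allowed_top = {"schema_version", "units", "modes", "states", "couplings"}
        unknown = set(d) - allowed_top
        if unknown:
            raise ValueError(f"unknown top-level keys in model file: {sorted(unknown)}")
        modes = []
        for m in d["modes"]:
            _check_keys(m, {"index", "omega_cm1", "symmetry"}, "mode")
            modes.append(
                ModeSpec(
                    index=int(m["index"]),
                    omega=float(m["omega_cm1"]) / CM1_PER_EV,
                    symmetry=m.get("symmetry", "A'"),
                )
            )
        states = []
        for s in d["states"]:
            _check_keys(
                s,
                {"label", "symmetry", "energy_ev", "gradient_ev", "dipole", "dipole_deriv"},
                "state",
            )
            states.append(
                StateSpec(
                    label=s["label"],
                    symmetry=s.get("symmetry", "A'"),
                    energy=float(s["energy_ev"]),
                    gradient=np.asarray(s["gradient_ev"], dtype=float),
                    dipole=np.asarray(s["dipole"], dtype=float),
                    dipole_deriv=(
                        np.asarray(s["dipole_deriv"], dtype=float)
                        if s.get("dipole_deriv") is not None
                        else None
                    ),
                )
            )
        couplings = []
        for c in d.get("couplings", []):
            _check_keys(c, {"bra", "ket", "lambda_ev"}, "coupling")
            couplings.append(
                CouplingSpec(bra=c["bra"], ket=c["ket"], lam=np.asarray(c["lambda_ev"]))
            )
        return cls(modes=tuple(modes), states=tuple(states), couplings=tuple(couplings))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "LVCModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_keys(entry: Mapping, allowed: set, what: str) -> None:
    unknown = set(entry) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {what} entry: {sorted(unknown)}")


def save_model(model: LVCModel, path) -> None:
    model.save(path)


def load_model(path) -> LVCModel:
    return LVCModel.load(path)


# ---------------------------------------------------------------------
# validation / audits
# ---------------------------------------------------------------------

def validate_model(model: LVCModel) -> list[str]:
    """Return a list of invariant violations (empty iff well formed)."""
    out: list[str] = []
    n = model.nmodes
    indices = [m.index for m in model.modes]
    if len(set(indices)) != len(indices):
        out.append("duplicate mode indices")
    if sorted(indices) != list(range(1, n + 1)):
        out.append(f"mode indices not contiguous 1..{n}: {indices}")
    for m in model.modes:
        if not m.omega > 0:
            out.append(f"mode {m.index}: omega must be > 0, got {m.omega}")
    labels = model.state_labels
    if len(set(labels)) != len(labels):
        out.append("duplicate state labels")
    for s in model.states:
        if not s.energy > 0:
            out.append(f"state {s.label}: energy must be > 0, got {s.energy}")
        if s.gradient.shape != (n,):
            out.append(
                f"state {s.label}: gradient length {s.gradient.shape} != nmodes {n}"
            )
        if s.dipole.shape != (3,):
            out.append(f"state {s.label}: dipole must have length 3")
        if s.dipole_deriv is not None and s.dipole_deriv.shape != (3, n):
            out.append(f"state {s.label}: dipole_deriv must have shape (3, {n})")
    seen: set[frozenset] = set()
    for c in model.couplings:
        if c.bra == c.ket:
            out.append(f"coupling ({c.bra},{c.ket}): bra == ket")
        for lbl in (c.bra, c.ket):
            if lbl not in labels:
                out.append(f"coupling references unknown state {lbl!r}")
        if c.pair in seen:
            out.append(f"duplicate unordered pair ({c.bra},{c.ket})")
        seen.add(c.pair)
        if c.lam.shape != (n,):
            out.append(
                f"coupling ({c.bra},{c.ket}): lambda length {c.lam.shape} != nmodes {n}"
            )
    return out


def symmetry_audit(model: LVCModel, totally_symmetric_label: str = "A'") -> list[str]:
    """Check gradients/couplings against two-irrep (e.g. Cs) selection rules.

    Intrastate gradients may live only on totally symmetric modes;
    an interstate coupling between irreps Gi, Gj may live only on modes
    of irrep Gi x Gj.
    """
    labels = {m.symmetry for m in model.modes} | {s.symmetry for s in model.states}
    labels.add(totally_symmetric_label)
    if len(labels) > 2:
        raise ValueError(
            f"symmetry audit needs a two-irrep group; found labels {sorted(labels)} "
            f"(totally symmetric: {totally_symmetric_label!r})"
        )
    ts = totally_symmetric_label
    other = next(iter(labels - {ts}), None)

    def product(a: str, b: str) -> str:
        return ts if a == b else other  # two-irrep group multiplication

    warnings: list[str] = []
    for s in model.states:
        for m, g in zip(model.modes, s.gradient):
            if g != 0.0 and m.symmetry != ts:
                warnings.append(
                    f"state {s.label}: nonzero gradient on non-totally-symmetric "
                    f"mode {m.index} ({m.symmetry})"
                )
    for c in model.couplings:
        gi = model.state(c.bra).symmetry
        gj = model.state(c.ket).symmetry
        target = product(gi, gj)
        for m, g in zip(model.modes, c.lam):
            if g != 0.0 and m.symmetry != target:
                warnings.append(
                    f"coupling ({c.bra},{c.ket}): nonzero component on mode "
                    f"{m.index} ({m.symmetry}), expected irrep {target}"
                )
    return warnings


def huang_rhys(model: LVCModel, state_label: str) -> np.ndarray:
    """Huang-Rhys factors S_j = lam_j^2 / (2 omega_j^2) for one state."""
    s = model.state(state_label)
    w = model.omegas
    return s.gradient**2 / (2.0 * w**2)


def apply_state_shift(model: LVCModel, labels: Iterable[str], delta: float) -> LVCModel:
    """Return a model with ``energy += delta`` on the listed states only."""
    labels = list(labels)
    for lbl in labels:
        model.state(lbl)  # raises on unknown label
    states = tuple(
        replace(s, energy=s.energy + delta) if s.label in labels else s
        for s in model.states
    )
    return replace(model, states=states)


# ---------------------------------------------------------------------
# random model generator
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class RandomRanges:
    """Sampling ranges for :func:`random_model` (min, max pairs).

    Frequencies in cm^-1; energies, gradient and coupling magnitudes in
    eV; dipole magnitudes in arbitrary units.  Vector components are
    drawn with magnitude uniform in the range and a random sign.
    """

    omega_cm1: tuple[float, float] = (400.0, 1700.0)
    energy_ev: tuple[float, float] = (4.0, 7.0)
    lam_ev: tuple[float, float] = (0.0, 0.12)
    dipole: tuple[float, float] = (0.2, 1.0)

    def validate(self) -> None:
        for name in ("omega_cm1", "energy_ev", "lam_ev", "dipole"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range {name}: min {lo} > max {hi}")


def random_model(
    nmodes: int,
    nstates: int,
    seed: int,
    ranges: RandomRanges | None = None,
    coupling_zero_fraction: float = 0.0,
) -> LVCModel:
    """Deterministic seeded model generator (numpy PCG64 ``default_rng``).

    All scalar magnitudes are drawn uniformly inside the given ranges;
    signs of gradient/coupling/dipole components are +-1 with equal
    probability.  ``coupling_zero_fraction`` zeroes that fraction of the
    state pairs (rounded down).
    """
    if nmodes < 1 or nstates < 1:
        raise ValueError("nmodes and nstates must be >= 1")
    ranges = ranges or RandomRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)

    def draw(lo_hi, size=None):
        lo, hi = lo_hi
        return rng.uniform(lo, hi, size=size)

    def signed(lo_hi, size):
        mag = draw(lo_hi, size)
        return mag * rng.choice([-1.0, 1.0], size=size)

    omegas = np.sort(draw(ranges.omega_cm1, nmodes)) / CM1_PER_EV
    modes = tuple(
        ModeSpec(index=j + 1, omega=float(w), symmetry="A'")
        for j, w in enumerate(omegas)
    )
    states = []
    for i in range(nstates):
        states.append(
            StateSpec(
                label=f"S{i + 1}",
                symmetry="A'",
                energy=float(draw(ranges.energy_ev)),
                gradient=signed(ranges.lam_ev, nmodes),
                dipole=signed(ranges.dipole, 3),
            )
        )
    pairs = [
        (states[i].label, states[j].label)
        for i in range(nstates)
        for j in range(i + 1, nstates)
    ]
    nzero = int(len(pairs) * coupling_zero_fraction)
    zero_idx = set(rng.choice(len(pairs), size=nzero, replace=False)) if nzero else set()
    couplings = []
    for p, (a, b) in enumerate(pairs):
        lam = signed(ranges.lam_ev, nmodes)
        if p in zero_idx:
            lam = np.zeros(nmodes)
        couplings.append(CouplingSpec(bra=a, ket=b, lam=lam))
    return LVCModel(modes=modes, states=tuple(states), couplings=tuple(couplings))
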