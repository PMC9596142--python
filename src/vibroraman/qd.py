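"""Exact quantum dynamics on LVC Hamiltonians in a truncated product basis.

The vibrational basis is a graded-lexicographically ordered set of
harmonic-oscillator occupation vectors (state-major replication over the
electronic states).  Matrix elements use q_j = (a_j + a_j^dag)/sqrt(2),
so <n+1_j| q_j |n> = sqrt((n_j + 1)/2).  The Hamiltonian is assembled as
a real symmetric sparse matrix, hence exactly Hermitian.

Propagation is numerically exact: dense eigendecomposition up to a
dimension switch, Krylov exponential action (``expm_multiply``) above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .model import LVCModel

__all__ = [
    "BasisSpec",
    "VibronicBasis",
    "Wavepacket",
    "HamiltonianOperator",
    "Trajectory",
    "CrossCorrelations",
    "enumerate_basis",
    "build_hamiltonian",
    "initial_wavepacket",
    "propagate",
    "cross_correlations",
    "eigen_correlations",
    "sum_over_states_alpha",
    "apply_dipole_operator",
    "convergence_check",
    "time_grid",
]

#: dimension above which propagation switches to Krylov and below which
#: dense diagonalization is used (also the sum-over-states hard cap)
DENSE_CAP = 4000


def time_grid(dt: float, tmax: float) -> np.ndarray:
    """Uniform grid 0, dt, ..., >= tmax (internal hbar/eV units)."""
    n = int(np.ceil(tmax / dt))
    return dt * np.arange(n + 1)


@dataclass(frozen=True)
class BasisSpec:
    """Truncation of the harmonic product basis.

    ``n_max`` is the per-mode maximum quantum number (scalar broadcast or
    sequence), ``n_tot`` the cap on the total number of quanta.
    """

    n_max: int | Sequence[int]
    n_tot: int
    hard_cap: int = 200_000

    def n_max_vector(self, nmodes: int) -> np.ndarray:
        n = np.broadcast_to(np.asarray(self.n_max, dtype=int), (nmodes,)).copy()
        if np.any(n < 1):
            raise ValueError("per-mode n_max must be >= 1")
        if self.n_tot < 1:
            raise ValueError("n_tot must be >= 1")
        return n

    def grown(self, extra: int) -> "BasisSpec":
        n_max = np.asarray(self.n_max) + extra
        n_max = n_max if n_max.ndim else int(n_max)
        return BasisSpec(n_max=n_max, n_tot=self.n_tot + extra, hard_cap=self.hard_cap)


class VibronicBasis:
    """Product basis |electronic state; occupation vector>.

    Ordering is state-major; within a state the occupation vectors are
    graded (by total quanta) then lexicographically descending, e.g. for
    2 modes: (0,0), (1,0), (0,1), (2,0), (1,1), (0,2).
    """

    def __init__(self, occs: np.ndarray, nstates: int):
        self.occs = np.asarray(occs, dtype=np.int32)
        self.nvib, self.nmodes = self.occs.shape
        self.nstates = int(nstates)
        self.dim = self.nvib * self.nstates
        self._lookup = {tuple(o): i for i, o in enumerate(self.occs.tolist())}

    def vib_index(self, occ: Sequence[int]) -> int:
        try:
            return self._lookup[tuple(int(x) for x in occ)]
        except KeyError:
            raise KeyError(f"occupation {tuple(occ)} not in basis") from None

    def index(self, state: int, occ: Sequence[int]) -> int:
        return state * self.nvib + self.vib_index(occ)

    def vacuum_index(self, state: int) -> int:
        return state * self.nvib  # vacuum is always the first vib element

    def fundamental_index(self, state: int, mode: int) -> int:
        """Index of |state; 0 + 1_f> for 1-based mode index ``mode``."""
        occ = np.zeros(self.nmodes, dtype=int)
        occ[mode - 1] = 1
        return self.index(state, occ)

    def elements(self):
        for s in range(self.nstates):
            for o in self.occs:
                yield s, tuple(int(x) for x in o)


def enumerate_basis(nmodes: int, spec: BasisSpec, nstates: int) -> VibronicBasis:
    """Enumerate all occupations with sum(n) <= n_tot and n_j <= n_max_j."""
    n_max = spec.n_max_vector(nmodes)
    n_tot = spec.n_tot

    def gen(j: int, budget: int):
        if j == nmodes:
            yield ()
            return
        for n in range(min(int(n_max[j]), budget) + 1):
            for rest in gen(j + 1, budget - n):
                yield (n,) + rest

    occs = sorted(gen(0, n_tot), key=lambda o: (sum(o), tuple(-x for x in o)))
    dim = len(occs) * nstates
    if dim > spec.hard_cap:
        raise ValueError(
            f"basis dimension {dim} exceeds hard cap {spec.hard_cap}; "
            "reduce n_tot/n_max or raise BasisSpec.hard_cap"
        )
    return VibronicBasis(np.array(occs, dtype=np.int32), nstates)


# ---------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------

def _ladder(basis: VibronicBasis, mode: int):
    """Raising-operator map for 1-based ``mode`` within the vib basis.

    Returns (targets, coeffs, inside) where ``targets[i]`` is the index
    of occ_i + e_mode (or -1 when the step leaves the truncated basis),
    ``coeffs[i] = sqrt((n_mode + 1)/2)`` and ``inside`` masks kept steps.
    """
    j = mode - 1
    occs = basis.occs
    coeffs = np.sqrt((occs[:, j] + 1) / 2.0)
    targets = np.full(basis.nvib, -1, dtype=np.int64)
    for i, occ in enumerate(occs):
        up = occ.copy()
        up[j] += 1
        t = basis._lookup.get(tuple(int(x) for x in up))
        if t is not None:
            targets[i] = t
    inside = targets >= 0
    return targets, coeffs, inside


def position_operator(basis: VibronicBasis, mode: int) -> sp.csr_matrix:
    """Symmetric q_mode = (a + a^dag)/sqrt(2) on the vibrational basis."""
    targets, coeffs, inside = _ladder(basis, mode)
    rows = targets[inside]
    cols = np.nonzero(inside)[0]
    vals = coeffs[inside]
    q = sp.coo_matrix(
        (np.concatenate([vals, vals]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(basis.nvib, basis.nvib),
    )
    return q.tocsr()


@dataclass
class HamiltonianOperator:
    """Sparse Hermitian LVC Hamiltonian tied to its basis."""

    matrix: sp.csr_matrix
    basis: VibronicBasis

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def __matmul__(self, vec: np.ndarray) -> np.ndarray:
        return self.matrix @ vec


def build_hamiltonian(model: LVCModel, basis: VibronicBasis) -> HamiltonianOperator:
    if basis.nmodes != model.nmodes or basis.nstates != model.nstates:
        raise ValueError(
            f"basis ({basis.nmodes} modes, {basis.nstates} states) does not match "
            f"model ({model.nmodes} modes, {model.nstates} states)"
        )
    w = model.omegas
    vib_diag = basis.occs @ w + 0.5 * w.sum()  # sum_j (n_j + 1/2) omega_j
    qs = [position_operator(basis, j + 1) for j in range(model.nmodes)]
    lam = model.coupling_matrix()
    blocks = [[None] * model.nstates for _ in range(model.nstates)]
    for i, s in enumerate(model.states):
        block = sp.diags(s.energy + vib_diag)
        for j in range(model.nmodes):
            if s.gradient[j] != 0.0:
                block = block + s.gradient[j] * qs[j]
        blocks[i][i] = block
    for i in range(model.nstates):
        for k in range(i + 1, model.nstates):
            if np.any(lam[i, k]):
                off = sum(lam[i, k][j] * qs[j] for j in range(model.nmodes) if lam[i, k][j])
                blocks[i][k] = off
                blocks[k][i] = off
    h = sp.bmat(blocks, format="csr")
    return HamiltonianOperator(matrix=h, basis=basis)


@dataclass
class Wavepacket:
    amplitudes: np.ndarray
    basis: VibronicBasis

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.amplitudes.shape != (self.basis.dim,):
            raise ValueError("amplitude vector does not match basis dimension")
        if not np.all(np.isfinite(self.amplitudes.view(float))):
            raise ValueError("non-finite amplitudes")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


def initial_wavepacket(basis: VibronicBasis, state: int) -> Wavepacket:
    """|Psi(0)> = |d_state; 0>: ground vibrational state vertically excited."""
    amps = np.zeros(basis.dim, dtype=complex)
    amps[basis.vacuum_index(state)] = 1.0
    return Wavepacket(amps, basis)


# ---------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------

@dataclass
class Trajectory:
    """psi(t) on a uniform grid; amplitudes has shape (nt, dim)."""

    tgrid: np.ndarray
    amplitudes: np.ndarray
    basis: VibronicBasis
    initial_state: int | None = None
    method: str = "eigh"

    def __len__(self) -> int:
        return len(self.tgrid)

    def __getitem__(self, i: int) -> Wavepacket:
        return Wavepacket(self.amplitudes[i], self.basis)

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.amplitudes, axis=1)

    def electronic_populations(self) -> np.ndarray:
        """(nt, nstates) populations of each electronic block."""
        nvib = self.basis.nvib
        p = np.abs(self.amplitudes) ** 2
        return p.reshape(len(self.tgrid), self.basis.nstates, nvib).sum(axis=2)


def _check_uniform(tgrid: np.ndarray) -> float:
    tgrid = np.asarray(tgrid, dtype=float)
    if tgrid.ndim != 1 or len(tgrid) < 2 or tgrid[0] != 0.0:
        raise ValueError("time grid must be 1D, start at 0 and have >= 2 points")
    dts = np.diff(tgrid)
    if not np.allclose(dts, dts[0], rtol=1e-12, atol=1e-12):
        raise ValueError("time grid must be uniform")
    return float(dts[0])


def propagate(
    H: HamiltonianOperator,
    psi0: Wavepacket,
    tgrid: np.ndarray,
    method: str = "auto",
) -> Trajectory:
    """psi(t) = exp(-i H t) psi(0) on a uniform grid starting at 0."""
    dt = _check_uniform(tgrid)
    if method == "auto":
        method = "eigh" if H.dim <= DENSE_CAP else "krylov"
    if method == "eigh":
        evals, vecs = np.linalg.eigh(H.dense())
        c = vecs.T @ psi0.amplitudes
        phases = np.exp(-1j * np.outer(np.asarray(tgrid), evals))  # (nt, dim)
        amps = (phases * c) @ vecs.T
    elif method == "krylov":
        step = -1j * dt * H.matrix.astype(complex)
        amps = np.empty((len(tgrid), H.dim), dtype=complex)
        amps[0] = psi0.amplitudes
        for i in range(1, len(tgrid)):
            amps[i] = expm_multiply(step, amps[i - 1])
    else:
        raise ValueError(f"unknown propagation method {method!r}")
    traj = Trajectory(np.asarray(tgrid, float), amps, H.basis, method=method)
    drift = np.max(np.abs(traj.norms - psi0.norm))
    if drift > 1e-9:
        warnings.warn(f"propagation norm drift {drift:.2e} exceeds 1e-9")
    return traj


# ---------------------------------------------------------------------
# correlation functions
# ---------------------------------------------------------------------

@dataclass
class CrossCorrelations:
    """C^{km}_f(t) = <d_k; 0+1_f| exp(-iHt) |d_m; 0> for one initial state m.

    ``values`` has shape (nstates, nmodes+1, nt); the f = 0 slot stores
    the vacuum bra <d_k; 0| used by the absorption spectrum, slot f >= 1
    the fundamental of 1-based mode f.
    """

    tgrid: np.ndarray
    values: np.ndarray
    bra_labels: list[str]
    initial_label: str
    e_g0: float

    def get(self, k_label: str, f: int) -> np.ndarray:
        return self.values[self.bra_labels.index(k_label), f]


def cross_correlations(
    model: LVCModel, basis: VibronicBasis, traj: Trajectory, initial_state: int
) -> CrossCorrelations:
    """Read cross-correlations off a stored trajectory of |d_m; 0>."""
    if basis.nmodes < 1:
        raise ValueError("empty mode set")
    nt = len(traj.tgrid)
    vals = np.empty((model.nstates, model.nmodes + 1, nt), dtype=complex)
    for k in range(model.nstates):
        vals[k, 0] = traj.amplitudes[:, basis.vacuum_index(k)]
        for f in range(1, model.nmodes + 1):
            try:
                idx = basis.fundamental_index(k, f)
            except KeyError:
                raise ValueError(
                    f"basis lacks fundamental |0+1_{f}> (n_tot/n_max too small)"
                ) from None
            vals[k, f] = traj.amplitudes[:, idx]
    return CrossCorrelations(
        tgrid=traj.tgrid,
        values=vals,
        bra_labels=model.state_labels,
        initial_label=model.states[initial_state].label,
        e_g0=model.zpe,
    )


def eigen_correlations(
    model: LVCModel,
    basis: VibronicBasis,
    initial_states: Sequence[int],
    tgrid: np.ndarray,
) -> dict[str, CrossCorrelations]:
    """Cross-correlations for several initial states without storing
    full trajectories (single diagonalization, selected rows only).

    Falls back to step-wise Krylov propagation above the dense cap.
    """
    _check_uniform(tgrid)
    tgrid = np.asarray(tgrid, dtype=float)
    H = build_hamiltonian(model, basis)
    rows = []
    for k in range(model.nstates):
        rows.append(basis.vacuum_index(k))
        for f in range(1, model.nmodes + 1):
            rows.append(basis.fundamental_index(k, f))
    rows = np.array(rows)
    nslots = model.nmodes + 1
    out: dict[str, CrossCorrelations] = {}
    if H.dim <= DENSE_CAP:
        evals, vecs = np.linalg.eigh(H.dense())
        phases = np.exp(-1j * np.outer(evals, tgrid))  # (dim, nt)
        for m in initial_states:
            c = vecs[basis.vacuum_index(m)]  # real eigenvectors
            weights = vecs[rows] * c  # (nrows, dim)
            vals = (weights @ phases).reshape(model.nstates, nslots, len(tgrid))
            out[model.states[m].label] = CrossCorrelations(
                tgrid=tgrid,
                values=vals,
                bra_labels=model.state_labels,
                initial_label=model.states[m].label,
                e_g0=model.zpe,
            )
    else:
        dt = float(tgrid[1] - tgrid[0])
        step = -1j * dt * H.matrix.astype(complex)
        for m in initial_states:
            psi = initial_wavepacket(basis, m).amplitudes
            vals = np.empty((len(rows), len(tgrid)), dtype=complex)
            vals[:, 0] = psi[rows]
            for i in range(1, len(tgrid)):
                psi = expm_multiply(step, psi)
                vals[:, i] = psi[rows]
            out[model.states[m].label] = CrossCorrelations(
                tgrid=tgrid,
                values=vals.reshape(model.nstates, nslots, len(tgrid)),
                bra_labels=model.state_labels,
                initial_label=model.states[m].label,
                e_g0=model.zpe,
            )
    return out


# ---------------------------------------------------------------------
# sum-over-states oracle
# ---------------------------------------------------------------------

def sum_over_states_alpha(
    model: LVCModel,
    basis: VibronicBasis,
    omega_grid: np.ndarray,
    gamma: float,
    f: int,
    mu_prime: np.ndarray | None = None,
) -> np.ndarray:
    """Transition polarizability alpha^{f0}_{rho sigma}(omega_I), (nw, 3, 3).

    Brute-force spectral sum over the eigenpairs of the full vibronic
    Hamiltonian:

        alpha = sum_a  mu_eff(a, f) (x) mu_eff(a, 0)
                       / (E_a - i gamma - E_g0 - omega_I)

    with state-independent gamma.  ``f = 0`` gives the Rayleigh/absorption
    tensor (vacuum on both sides).  ``mu_prime`` (3, nmodes) switches on
    the Herzberg-Teller dipole term and requires a single-state model.
    """
    if basis.dim > DENSE_CAP:
        raise ValueError(f"dimension {basis.dim} exceeds dense cap {DENSE_CAP}")
    if mu_prime is not None and model.nstates != 1:
        raise ValueError("Herzberg-Teller sum-over-states requires a single-state model")
    H = build_hamiltonian(model, basis)
    evals, vecs = np.linalg.eigh(H.dense())
    mu = model.dipole_matrix()  # (nstates, 3)

    def side_vectors(slot: int) -> np.ndarray:
        """(3, dim) overlap of mu_rho(q)|slot> with each eigenvector."""
        u = np.zeros((3, basis.dim))
        for k in range(model.nstates):
            idx = basis.vacuum_index(k) if slot == 0 else basis.fundamental_index(k, slot)
            u[:, idx] += mu[k]
            if mu_prime is not None:
                vib = np.zeros(basis.nvib)
                vib[idx - k * basis.nvib] = 1.0
                for j in range(model.nmodes):
                    qv = position_operator(basis, j + 1) @ vib
                    lo = k * basis.nvib
                    u[:, lo : lo + basis.nvib] += np.outer(mu_prime[:, j], qv)
        return u @ vecs  # (3, dim) in the eigenbasis

    uf = side_vectors(f)
    u0 = side_vectors(0)
    omega_grid = np.asarray(omega_grid, dtype=float)
    denom = evals[None, :] - 1j * gamma - model.zpe - omega_grid[:, None]
    return np.einsum("ra,sa,wa->wrs", uf, u0, 1.0 / denom)


# ---------------------------------------------------------------------
# dipole operator (Herzberg-Teller machinery)
# ---------------------------------------------------------------------

def apply_dipole_operator(
    mu0: np.ndarray,
    mu_prime: np.ndarray | None,
    psi: Wavepacket,
) -> tuple[list[Wavepacket], np.ndarray]:
    """Apply mu(q) = mu0 + sum_j mu'_j q_j to a single-state wavepacket.

    Returns one wavepacket per Cartesian component plus the amplitude
    squared dropped at the basis boundary (raising steps leaving the
    truncated basis), one entry per component.
    """
    basis = psi.basis
    if basis.nstates != 1:
        raise ValueError("dipole operator application requires a single-state basis")
    mu0 = np.asarray(mu0, dtype=float)
    amps = psi.amplitudes
    out = [mu0[r] * amps.copy() for r in range(3)]
    dropped = np.zeros(3)
    if mu_prime is not None:
        mu_prime = np.asarray(mu_prime, dtype=float)
        if mu_prime.shape != (3, basis.nmodes):
            raise ValueError(f"mu_prime must have shape (3, {basis.nmodes})")
        for j in range(basis.nmodes):
            if not np.any(mu_prime[:, j]):
                continue
            q = position_operator(basis, j + 1)
            qpsi = q @ amps
            targets, coeffs, inside = _ladder(basis, j + 1)
            lost = np.sum(np.abs(amps[~inside] * coeffs[~inside]) ** 2)
            for r in range(3):
                out[r] += mu_prime[r, j] * qpsi
                dropped[r] += mu_prime[r, j] ** 2 * lost
    return [Wavepacket(o, basis) for o in out], dropped


# ---------------------------------------------------------------------
# convergence report
# ---------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    observable: str
    n_tot: int
    n_tot_ref: int
    max_relative_change: float
    tolerance: float

    @property
    def converged(self) -> bool:
        return self.max_relative_change <= self.tolerance


def convergence_check(
    model: LVCModel,
    spec: BasisSpec,
    observable: str,
    settings=None,
    tolerance: float = 1e-3,
) -> ConvergenceReport:
    """Recompute a named spectrum with n_tot + 2 and report the change.

    ``observable`` is ``"vrr"`` or ``"absorption"``; the change is the
    max pointwise deviation normalized by the peak of the reference.
    """
    from . import spectra  # deferred: spectra imports this module

    if observable not in {"vrr", "absorption"}:
        raise ValueError("observable must be 'vrr' or 'absorption'")
    base = settings or spectra.SpectrumSettings()
    lo = spectra.replace_settings(base, n_tot=spec.n_tot, n_max=None)
    hi_spec = spec.grown(2)
    hi = spectra.replace_settings(base, n_tot=hi_spec.n_tot, n_max=None)

    if observable == "vrr":
        a = spectra.compute_vrr(model, "lvc", settings=lo).intensities
        b = spectra.compute_vrr(model, "lvc", settings=hi).intensities
    else:
        a = spectra.absorption_spectrum(model, "lvc", hwhm=0.04, settings=lo).intensity
        b = spectra.absorption_spectrum(model, "lvc", hwhm=0.04, settings=hi).intensity
    scale = np.max(np.abs(b))
    change = 0.0 if scale == 0 else float(np.max(np.abs(a - b)) / scale)
    return ConvergenceReport(
        observable=observable,
        n_tot=spec.n_tot,
        n_tot_ref=hi_spec.n_tot,
        max_relative_change=change,
        tolerance=tolerance,
    )
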