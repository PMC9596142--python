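"""Physical unit conventions.

Internally every energy-like quantity (frequencies, vertical energies,
gradients, damping constants) is carried in eV, coordinates are
dimensionless, and time is measured in hbar/eV (hbar = 1).  Model files
store frequencies in cm^-1 and energies in eV.
"""

from __future__ import annotations

import numpy as np

#: cm^-1 per eV (CODATA-derived, pinned).
CM1_PER_EV = 8065.543937

#: Product wavelength[nm] * photon energy[eV] (pinned).
NM_TIMES_EV = 1239.841984

#: Femtoseconds per internal time unit hbar/eV (pinned).
FS_PER_HBAR_EV = 0.658211957

_ENERGY_UNITS = {"eV", "cm-1", "nm"}
_TIME_UNITS = {"fs", "hbar/eV"}


def convert(value, from_unit: str, to_unit: str):
    """Convert between the supported units.

    Energy-like units: ``eV``, ``cm-1``, ``nm`` (photon wavelength,
    reciprocal relation); time units: ``fs``, ``hbar/eV``.  Mixing an
    energy unit with a time unit raises ``ValueError``.
    """
    value = np.asarray(value, dtype=float)
    if value.ndim == 0:
        value = float(value)
    if from_unit == to_unit:
        return value
    if from_unit in _ENERGY_UNITS and to_unit in _ENERGY_UNITS:
        ev = _to_ev(value, from_unit)
        return _from_ev(ev, to_unit)
    if from_unit in _TIME_UNITS and to_unit in _TIME_UNITS:
        if from_unit == "fs":
            return value / FS_PER_HBAR_EV
        return value * FS_PER_HBAR_EV
    raise ValueError(
        f"unsupported unit pair {from_unit!r} -> {to_unit!r}; "
        f"energy units: {sorted(_ENERGY_UNITS)}, time units: {sorted(_TIME_UNITS)}"
    )


def _to_ev(value, unit):
    if unit == "eV":
        return value
    if unit == "cm-1":
        return value / CM1_PER_EV
    if unit == "nm":
        return NM_TIMES_EV / value
    raise ValueError(f"unknown energy unit {unit!r}")


def _from_ev(ev, unit):
    if unit == "eV":
        return ev
    if unit == "cm-1":
        return ev * CM1_PER_EV
    if unit == "nm":
        return NM_TIMES_EV / ev
    raise ValueError(f"unknown energy unit {unit!r}")
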