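"""Optional HDF5 cache for cross-correlation functions.

Layout: ``/tgrid`` plus ``/corr/{k}/{f}/re`` and ``/corr/{k}/{f}/im``
for every bra state label ``k`` and slot ``f`` (0 = vacuum bra,
f >= 1 the fundamental of 1-based mode f), one file per initial state.
"""

from __future__ import annotations

import numpy as np

from .qd import CrossCorrelations

__all__ = ["save_correlations", "load_correlations"]


def save_correlations(path, corr: CrossCorrelations) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("tgrid", data=corr.tgrid)
        fh.attrs["initial_label"] = corr.initial_label
        fh.attrs["e_g0"] = corr.e_g0
        for ki, k in enumerate(corr.bra_labels):
            for f in range(corr.values.shape[1]):
                grp = fh.require_group(f"corr/{k}/{f}")
                grp.create_dataset("re", data=corr.values[ki, f].real)
                grp.create_dataset("im", data=corr.values[ki, f].imag)


def load_correlations(path) -> CrossCorrelations:
    import h5py

    with h5py.File(path, "r") as fh:
        tgrid = fh["tgrid"][...]
        labels = list(fh["corr"])
        nslots = len(fh[f"corr/{labels[0]}"])
        values = np.empty((len(labels), nslots, len(tgrid)), dtype=complex)
        for ki, k in enumerate(labels):
            for f in range(nslots):
                values[ki, f] = fh[f"corr/{k}/{f}/re"][...] + 1j * fh[f"corr/{k}/{f}/im"][...]
        return CrossCorrelations(
            tgrid=tgrid,
            values=values,
            bra_labels=labels,
            initial_label=fh.attrs["initial_label"],
            e_g0=float(fh.attrs["e_g0"]),
        )
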