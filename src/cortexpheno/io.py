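"""File round-trip helpers for the non-tabular artifacts.

Count matrices write themselves (MTX + TSV sidecars or dense CSV, see
:class:`~cortexpheno.containers.CountMatrix`); tissue has CSV + JSON
truth (see :class:`~cortexpheno.stereology.Tissue`).  This module adds
the columnar trace archive (HDF5, one group per slice) and hypnogram
CSVs.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .synthetic import TraceSet


def write_tracesets(path: str | os.PathLike, tracesets: list[TraceSet]) -> None:
    """One HDF5 group per slice: trace matrix, neuropil matrix, depth vector, metadata."""
    with h5py.File(path, "w") as fh:
        for ts in tracesets:
            grp = fh.create_group(ts.slice_id)
            grp.create_dataset("traces", data=ts.traces, compression="gzip")
            grp.create_dataset("neuropil", data=ts.neuropil, compression="gzip")
            grp.create_dataset("depths_um", data=ts.depths_um)
            grp.attrs["frame_rate_hz"] = ts.frame_rate_hz
            grp.attrs["animal_id"] = ts.animal_id
            grp.attrs["genotype"] = ts.genotype


def read_tracesets(path: str | os.PathLike) -> list[TraceSet]:
    out = []
    with h5py.File(path, "r") as fh:
        for slice_id in sorted(fh):
            grp = fh[slice_id]
            out.append(
                TraceSet(
                    traces=np.asarray(grp["traces"]),
                    neuropil=np.asarray(grp["neuropil"]),
                    depths_um=np.asarray(grp["depths_um"]),
                    frame_rate_hz=float(grp.attrs["frame_rate_hz"]),
                    slice_id=slice_id,
                    animal_id=str(grp.attrs["animal_id"]),
                    genotype=str(grp.attrs["genotype"]),
                )
            )
    return out


def write_hypnograms(path: str | os.PathLike, hypnograms: pd.DataFrame) -> None:
    hypnograms.to_csv(path, index=False, columns=["subject", "genotype", "start_s", "duration_s", "state"])


def read_hypnograms(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
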