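"""Serialization: rasters and result tables to CSV, array bundles to HDF5.

Conventions: times are in ms, weights dimensionless, changes in percent;
CSV files carry a ``#``-prefixed header comment stating units.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .inputs import SpikeRaster

__all__ = [
    "raster_to_csv",
    "raster_from_csv",
    "spikes_to_csv",
    "weights_to_hdf5",
    "loss_record_to_csv",
    "curve_to_csv",
]


def raster_to_csv(raster: SpikeRaster, path, sidecar: dict | None = None) -> None:
    """Write a raster as (channel_index, spike_time_ms) rows.

    ``sidecar`` (e.g. the generating spec and seed) is written next to the
    CSV as ``<path>.json`` together with the channel count and duration.
    """
    path = Path(path)
    rows = [
        (c, t) for c, ts in enumerate(raster.spikes) for t in ts
    ]
    df = pd.DataFrame(rows, columns=["channel_index", "spike_time_ms"])
    with open(path, "w") as fh:
        fh.write("# presynaptic spike raster; times in ms\n")
        df.to_csv(fh, index=False)
    meta = {"n_channels": raster.n_channels, "duration_ms": raster.duration}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def raster_from_csv(path) -> SpikeRaster:
    """Read a raster written by :func:`raster_to_csv` (requires the sidecar)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    meta = json.loads(Path(str(path) + ".json").read_text())
    n = int(meta["n_channels"])
    spikes = [
        df.loc[df.channel_index == c, "spike_time_ms"].to_numpy() for c in range(n)
    ]
    return SpikeRaster(n, spikes, float(meta["duration_ms"]))


def spikes_to_csv(spike_times_by_unit, path, unit_label: str = "neuron_index") -> None:
    """Write per-unit output spike times (ms) as tidy rows."""
    rows = [
        (u, t) for u, ts in enumerate(spike_times_by_unit) for t in np.atleast_1d(ts)
    ]
    df = pd.DataFrame(rows, columns=[unit_label, "spike_time_ms"])
    with open(path, "w") as fh:
        fh.write("# output spike times in ms\n")
        df.to_csv(fh, index=False)


def weights_to_hdf5(path, **arrays) -> None:
    """Store named arrays (e.g. epoch x channel weight trajectories) in HDF5."""
    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))


def loss_record_to_csv(record, path) -> None:
    """Write per-epoch loss bookkeeping (epoch, L, L_norm, cum_v)."""
    df = pd.DataFrame({
        "epoch": np.arange(record.loss.size),
        "loss": record.loss,
        "loss_norm": record.loss_norm,
        "cum_v": record.cum_v,
    })
    with open(path, "w") as fh:
        fh.write("# per-epoch cumulative prediction loss (dimensionless), "
                 "loss normalized to epoch 0, cumulative membrane potential\n")
        df.to_csv(fh, index=False)


def curve_to_csv(curve, path) -> None:
    """Write an StdpCurve (weight change in % of initial) as tidy CSV."""
    with open(path, "w") as fh:
        fh.write("# weight change of the subthreshold probe in % of its "
                 "initial value; delays in ms, frequencies in Hz\n")
        curve.to_frame().to_csv(fh, index=False)
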