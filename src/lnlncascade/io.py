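"""HDF5 persistence for recordings and fitted models.

A recording container stores the stimulus (``stimulus`` dataset with
``frame_rate_hz`` and ``bar_width_um`` attributes) and per-cell spike
counts under ``spikes/cellNN``.  Models are stored as HDF5 arrays with a
JSON sidecar of scalar hyperparameters.
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np

from .data import SpikeTrain, Stimulus
from .lnln import BasisNonlinearity, LNLNModel, OutputNonlinearity


def save_recording(path, stimulus: Stimulus, spikes: dict[int, SpikeTrain] | None = None):
    """Write a stimulus and optional spike trains to an HDF5 container."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("stimulus", data=stimulus.luminance)
        ds.attrs["frame_rate_hz"] = stimulus.frame_rate_hz
        ds.attrs["bar_width_um"] = stimulus.bar_width_um
        if spikes:
            grp = f.create_group("spikes")
            for cell, train in spikes.items():
                d = grp.create_dataset(f"cell{cell:02d}", data=train.counts)
                d.attrs["bin_width_s"] = train.bin_width_s


def load_recording(path):
    """Read a recording container; returns (Stimulus, {cell: SpikeTrain})."""
    with h5py.File(path, "r") as f:
        ds = f["stimulus"]
        stim = Stimulus(luminance=ds[()],
                        bar_width_um=float(ds.attrs["bar_width_um"]),
                        frame_rate_hz=float(ds.attrs["frame_rate_hz"]))
        spikes = {}
        if "spikes" in f:
            for name, d in f["spikes"].items():
                cell = int(name.removeprefix("cell"))
                spikes[cell] = SpikeTrain(counts=d[()],
                                          bin_width_s=float(d.attrs["bin_width_s"]))
    return stim, spikes


def load_spike_times_txt(path) -> np.ndarray:
    """One-column plain-text spike times in seconds."""
    times = np.loadtxt(path, ndmin=1)
    if times.ndim != 1:
        raise ValueError("expected a single column of spike times")
    return np.sort(times)


def save_model(path, model: LNLNModel, hyperparameters: dict | None = None):
    """Serialize a model: HDF5 arrays plus a JSON sidecar of scalars."""
    path = pathlib.Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=model.filters)
        f.create_dataset("nl_centers", data=model.nonlinearities[0].centers)
        f.create_dataset("nl_weights",
                         data=np.vstack([nl.weights for nl in model.nonlinearities]))
        f.attrs["nl_width"] = model.nonlinearities[0].width
        f.attrs["gain"] = model.output.gain
        f.attrs["threshold"] = model.output.threshold
        f.attrs["n_bars"] = model.n_bars
        f.attrs["n_lags"] = model.n_lags
    sidecar = {"gain": model.output.gain, "threshold": model.output.threshold,
               "n_subunits": model.n_subunits, "n_bars": model.n_bars,
               "n_lags": model.n_lags}
    if hyperparameters:
        sidecar["hyperparameters"] = hyperparameters
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> LNLNModel:
    with h5py.File(path, "r") as f:
        filters = f["filters"][()]
        centers = f["nl_centers"][()]
        weights = f["nl_weights"][()]
        width = float(f.attrs["nl_width"])
        out = OutputNonlinearity(gain=float(f.attrs["gain"]),
                                 threshold=float(f.attrs["threshold"]))
        n_bars = int(f.attrs["n_bars"])
        n_lags = int(f.attrs["n_lags"])
    nls = [BasisNonlinearity(centers=centers, width=width, weights=w)
           for w in weights]
    return LNLNModel(filters=filters, nonlinearities=nls, output=out,
                     n_bars=n_bars, n_lags=n_lags)
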