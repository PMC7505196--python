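"""Serialization: spike CSV/HDF5, network snapshots for exact re-runs."""

from __future__ import annotations

from typing import Optional, Tuple

import h5py
import numpy as np
import scipy.sparse as sp

from . import srnn_core as core
from .drive import InputProjection, OscillatorBank

__all__ = [
    "save_spikes_hdf5", "load_spikes_hdf5", "save_snapshot",
    "load_snapshot", "save_traces_hdf5", "load_traces_hdf5",
]

_POP_FIELDS = ("is_excitatory", "R", "C", "E_L", "V_theta", "V_reset",
               "I_tonic", "T_delay", "tau_ref", "G_ex", "G_in", "tau_ex",
               "tau_in", "E_ex", "E_in")


def save_spikes_hdf5(path, spikes: core.SpikeTrain,
                     meta: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("neuron_id", data=spikes.neurons)
        g.create_dataset("time_ms", data=spikes.times)
        g.attrs["duration_ms"] = spikes.duration
        g.attrs["size"] = spikes.size
        for k, v in (meta or {}).items():
            g.attrs[k] = v


def load_spikes_hdf5(path) -> core.SpikeTrain:
    with h5py.File(path, "r") as f:
        g = f["spikes"]
        return core.SpikeTrain(
            neurons=g["neuron_id"][...], times=g["time_ms"][...],
            duration=float(g.attrs["duration_ms"]),
            size=int(g.attrs["size"]),
        )


def save_snapshot(path, population: core.NeuronPopulation,
                  W: Optional[core.SynapticMatrix] = None,
                  bank: Optional[OscillatorBank] = None,
                  projection: Optional[InputProjection] = None,
                  W_out: Optional[np.ndarray] = None,
                  seeds: Optional[dict] = None) -> None:
    """Write everything needed to re-run a network bit-for-bit."""
    with h5py.File(path, "w") as f:
        g = f.create_group("population")
        g.attrs["size"] = population.size
        for name in _POP_FIELDS:
            g.create_dataset(name, data=getattr(population, name))
        if W is not None:
            m = W.magnitudes.tocsc()
            g = f.create_group("weights")
            g.create_dataset("data", data=m.data)
            g.create_dataset("indices", data=m.indices)
            g.create_dataset("indptr", data=m.indptr)
            g.attrs["shape"] = m.shape
            g.attrs["density"] = W.density
            g.attrs["sigma"] = W.sigma
            g.attrs["gain"] = W.gain
        if bank is not None:
            g = f.create_group("bank")
            g.create_dataset("f", data=bank.f)
            g.create_dataset("phi0", data=bank.phi0)
            g.attrs["A"] = bank.A
            g.attrs["variant"] = bank.variant
        if projection is not None:
            g = f.create_group("projection")
            g.create_dataset("M", data=projection.M)
            g.attrs["density"] = projection.density
            g.attrs["sigma"] = projection.sigma
        if W_out is not None:
            f.create_dataset("W_out", data=W_out)
        if seeds:
            g = f.create_group("seeds")
            for k, v in seeds.items():
                g.attrs[k] = v


def load_snapshot(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        g = f["population"]
        fields = {name: g[name][...] for name in _POP_FIELDS}
        out["population"] = core.NeuronPopulation(
            size=int(g.attrs["size"]), **fields)
        if "weights" in f:
            g = f["weights"]
            m = sp.csc_matrix(
                (g["data"][...], g["indices"][...], g["indptr"][...]),
                shape=tuple(g.attrs["shape"]))
            out["W"] = core.SynapticMatrix(
                magnitudes=m, density=float(g.attrs["density"]),
                sigma=float(g.attrs["sigma"]), gain=float(g.attrs["gain"]))
        if "bank" in f:
            g = f["bank"]
            out["bank"] = OscillatorBank(
                f=g["f"][...], phi0=g["phi0"][...],
                A=float(g.attrs["A"]), variant=str(g.attrs["variant"]))
        if "projection" in f:
            g = f["projection"]
            out["projection"] = InputProjection(
                M=g["M"][...], density=float(g.attrs["density"]),
                sigma=float(g.attrs["sigma"]))
        if "W_out" in f:
            out["W_out"] = f["W_out"][...]
        if "seeds" in f:
            out["seeds"] = dict(f["seeds"].attrs)
    return out


def save_traces_hdf5(path, traces: dict) -> None:
    """Recorded V/g/I_ext arrays with their time axis as an attribute."""
    with h5py.File(path, "a") as f:
        g = f.require_group("traces")
        for key in ("V", "g_ex", "g_in", "I_ext"):
            if key in traces:
                if key in g:
                    del g[key]
                d = g.create_dataset(key, data=traces[key])
                d.attrs["time_ms"] = traces["t_rec"]
        if "rate" in traces:
            if "rate" in g:
                del g["rate"]
            d = g.create_dataset("rate", data=traces["rate"])
            d.attrs["dt_ms"] = traces["dt"]


def load_traces_hdf5(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        g = f["traces"]
        for key in ("V", "g_ex", "g_in", "I_ext"):
            if key in g:
                out[key] = g[key][...]
                out["t_rec"] = g[key].attrs["time_ms"]
        if "rate" in g:
            out["rate"] = g["rate"][...]
            out["dt"] = float(g["rate"].attrs["dt_ms"])
    return out
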