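"""Serialisation: flat tables in CSV and HDF5 dialects.

Cell tables, edge tables, filter banks and spike tables all round-trip
through either format; wave schedules go to JSON.  HDF5 files carry the
construction metadata (rule tag, seed, class matrix) as attributes /
sidecar JSON strings.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .background import WaveSchedule
from .connectome import ConnectionSet
from .netsim import SpikeData


def save_edges_csv(conns: ConnectionSet, path) -> None:
    conns.to_frame().assign(delay=conns.delay).to_csv(path, index=False)


def save_edges_h5(conns: ConnectionSet, path, group: str = "edges") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name in ("source", "target", "n_syn", "weight"):
            g.create_dataset(name, data=getattr(conns, name))
        g.attrs["delay"] = conns.delay
        g.attrs["kind"] = conns.kind
        g.attrs["meta"] = json.dumps({"rule_tag": conns.rule_tag,
                                      "seed": conns.seed})


def load_edges_h5(path, group: str = "edges") -> ConnectionSet:
    with h5py.File(path, "r") as f:
        g = f[group]
        meta = json.loads(g.attrs["meta"])
        return ConnectionSet(g["source"][:], g["target"][:], g["n_syn"][:],
                             g["weight"][:], float(g.attrs["delay"]),
                             meta["rule_tag"], meta["seed"],
                             str(g.attrs["kind"]))


def save_cells_h5(cells: pd.DataFrame, path, group: str = "cells") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for col in ("cell_id", "x", "y", "z", "theta_assigned"):
            if col in cells:
                g.create_dataset(col, data=cells[col].to_numpy())
        g.create_dataset("cell_type",
                         data=cells["cell_type"].astype(str).to_numpy(),
                         dtype=h5py.string_dtype())
        g.create_dataset("is_core", data=cells["is_core"].to_numpy())


def load_cells_h5(path, group: str = "cells") -> pd.DataFrame:
    from .geometry import EI_CLASS
    with h5py.File(path, "r") as f:
        g = f[group]
        cells = pd.DataFrame({
            "cell_id": g["cell_id"][:],
            "cell_type": [s.decode() for s in g["cell_type"][:]],
            "x": g["x"][:], "y": g["y"][:], "z": g["z"][:],
            "is_core": g["is_core"][:].astype(bool),
        })
        if "theta_assigned" in g:
            cells["theta_assigned"] = g["theta_assigned"][:]
    cells["ei_class"] = cells["cell_type"].map(EI_CLASS)
    cells["cell_type"] = cells["cell_type"].astype("category")
    cells["ei_class"] = cells["ei_class"].astype("category")
    return cells


def save_spikes_csv(sd: SpikeData, path) -> None:
    sd.to_frame().to_csv(path, index=False)


def save_spikes_h5(spike_list, path) -> None:
    with h5py.File(path, "w") as f:
        for sd in spike_list:
            g = f.create_group(f"trial_{sd.trial}")
            g.create_dataset("cell_id", data=sd.cell_ids)
            g.create_dataset("time_ms", data=sd.times)
            g.attrs["n_cells"] = sd.n_cells
            g.attrs["t_max_ms"] = sd.t_max_ms
            for k, v in sd.acc.items():
                g.create_dataset(f"acc_{k}", data=v)


def load_spikes_h5(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            acc = {k[4:]: g[k][:] for k in g if k.startswith("acc_")}
            out.append(SpikeData(g["cell_id"][:], g["time_ms"][:],
                                 int(g.attrs["n_cells"]),
                                 float(g.attrs["t_max_ms"]),
                                 trial=int(name.split("_")[1]), acc=acc))
    return out


def save_schedule_json(schedule: WaveSchedule, path) -> None:
    with open(path, "w") as f:
        json.dump({
            "onset": schedule.onset.tolist(),
            "duration": schedule.duration.tolist(),
            "direction": schedule.direction.tolist(),
            "amplitude": schedule.amplitude.tolist(),
            "footprint_radius": schedule.footprint_radius,
            "width": schedule.width,
        }, f, indent=1)


def load_schedule_json(path) -> WaveSchedule:
    with open(path) as f:
        d = json.load(f)
    return WaveSchedule(np.asarray(d["onset"]), np.asarray(d["duration"]),
                        np.asarray(d["direction"]),
                        np.asarray(d["amplitude"]),
                        d["footprint_radius"], d["width"])


def save_filter_bank_csv(bank: pd.DataFrame, path) -> None:
    bank.to_csv(path, index=False)


def load_filter_bank_csv(path) -> pd.DataFrame:
    bank = pd.read_csv(path)
    bank["ftype"] = bank["ftype"].astype("category")
    return bank


def save_movie_h5(movie, path, group: str = "movie") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("frames", data=movie.frames, compression="gzip")
        g.attrs["dt_ms"] = movie.dt_ms
        g.attrs["pixel_deg"] = movie.pixel_deg
        g.attrs["name"] = movie.name


def load_movie_h5(path, group: str = "movie"):
    from .stimuli import StimulusMovie
    with h5py.File(path, "r") as f:
        g = f[group]
        return StimulusMovie(g["frames"][:], str(g.attrs["name"]),
                             float(g.attrs["dt_ms"]),
                             float(g.attrs["pixel_deg"]))
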