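"""On-disk containers: epoch HDF5/NPZ files and tidy response tables.

Epoch container layout (HDF5 datasets / NPZ keys):
``/data`` (trials x sensors x samples, float64), ``/fs`` (Hz), ``/t0``
(seconds), ``/sensors`` (sensor id strings), ``/condition``, ``/subject``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochSet
from .spectral import ResponseMap

__all__ = [
    "save_epochs", "load_epochs", "save_responses_tsv",
    "load_responses_tsv", "responses_to_frame", "save_json",
    "save_spectrum", "load_spectrum", "save_graph_tsv", "load_graph_tsv",
]


def save_epochs(epochs: EpochSet, path, sensor_id=None) -> None:
    """Write one EpochSet to HDF5 (.h5/.hdf5) or NPZ (.npz)."""
    path = Path(path)
    sensors = list(sensor_id) if sensor_id is not None else [
        f"s{i}" for i in range(epochs.data.shape[1])]
    if path.suffix == ".npz":
        np.savez(path, data=epochs.data, fs=epochs.fs, t0=epochs.t0,
                 sensors=np.array(sensors, dtype="U"),
                 condition=epochs.condition, subject=epochs.subject_id)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f["fs"] = epochs.fs
        f["t0"] = epochs.t0
        f.create_dataset("sensors", data=np.array(sensors, dtype="S"))
        f["condition"] = epochs.condition
        f["subject"] = epochs.subject_id


def load_epochs(path) -> tuple[EpochSet, list[str]]:
    """Read an epoch container; returns (EpochSet, sensor ids)."""
    path = Path(path)
    if path.suffix == ".npz":
        z = np.load(path, allow_pickle=False)
        es = EpochSet(subject_id=str(z["subject"]), condition=str(z["condition"]),
                      data=z["data"], fs=float(z["fs"]), t0=float(z["t0"]))
        return es, [str(s) for s in z["sensors"]]
    with h5py.File(path, "r") as f:
        es = EpochSet(
            subject_id=f["subject"][()].decode()
            if isinstance(f["subject"][()], bytes) else str(f["subject"][()]),
            condition=f["condition"][()].decode()
            if isinstance(f["condition"][()], bytes) else str(f["condition"][()]),
            data=f["data"][()], fs=float(f["fs"][()]), t0=float(f["t0"][()]))
        sensors = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["sensors"][()]]
    return es, sensors


def responses_to_frame(maps: list[ResponseMap]) -> pd.DataFrame:
    """Tidy table: subject, condition, sensor, f_target, value."""
    rows = []
    for m in maps:
        ids = m.node_id or tuple(f"s{i}" for i in range(m.values.size))
        for node, v in zip(ids, m.values):
            rows.append({"subject": m.subject_id, "condition": m.condition,
                         "sensor": node, "f_target": m.f_target,
                         "value": float(v)})
    return pd.DataFrame(rows, columns=["subject", "condition", "sensor",
                                       "f_target", "value"])


def save_responses_tsv(maps: list[ResponseMap], path) -> None:
    responses_to_frame(maps).to_csv(path, sep="\t", index=False,
                                    float_format="%.17g")


def load_responses_tsv(path) -> list[ResponseMap]:
    """Rebuild ResponseMaps from a tidy TSV, one per (subject, condition)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "sensor": str})
    out = []
    for (subj, cond), grp in df.groupby(["subject", "condition"], sort=True):
        out.append(ResponseMap(values=grp["value"].to_numpy(),
                               f_target=float(grp["f_target"].iloc[0]),
                               subject_id=subj, condition=str(cond),
                               node_id=tuple(grp["sensor"])))
    return out


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_spectrum(spectrum, path) -> None:
    """Write an AmplitudeSpectrum to HDF5 (/amplitudes, /freqs,
    /resolution, /corrected, /defined, /sensors)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=spectrum.amplitudes)
        f.create_dataset("freqs", data=spectrum.freqs)
        f["resolution"] = spectrum.resolution
        f["corrected"] = bool(spectrum.corrected)
        f.create_dataset("defined", data=spectrum.defined)
        ids = spectrum.sensor_id or tuple(
            f"s{i}" for i in range(spectrum.n_sensors))
        f.create_dataset("sensors", data=np.array(ids, dtype="S"))


def load_spectrum(path):
    from .spectral import AmplitudeSpectrum
    with h5py.File(path, "r") as f:
        return AmplitudeSpectrum(
            amplitudes=f["amplitudes"][()], freqs=f["freqs"][()],
            resolution=float(f["resolution"][()]),
            corrected=bool(f["corrected"][()]),
            defined=f["defined"][()].astype(bool),
            sensor_id=tuple(s.decode() for s in f["sensors"][()]))


def save_graph_tsv(graph, path) -> None:
    """Adjacency as an edge list (columns node_a, node_b); isolated nodes
    appear with an empty node_b."""
    rows = [{"node_a": a, "node_b": b}
            for a, b in (sorted(e) for e in graph.edges)]
    touched = {n for e in graph.edges for n in e}
    rows += [{"node_a": n, "node_b": ""} for n in graph.nodes
             if n not in touched]
    pd.DataFrame(sorted(rows, key=lambda r: (r["node_a"], r["node_b"])),
                 columns=["node_a", "node_b"]).to_csv(path, sep="\t",
                                                      index=False)


def load_graph_tsv(path):
    from .inference import AdjacencyGraph
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    nodes, edges = [], set()
    seen = set()
    for a, b in zip(df["node_a"], df["node_b"]):
        for n in (a, b):
            if n and n not in seen:
                seen.add(n)
                nodes.append(n)
        if a and b:
            edges.add(frozenset((a, b)))
    return AdjacencyGraph(nodes=tuple(sorted(nodes)),
                          edges=frozenset(edges))
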