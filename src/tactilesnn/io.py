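"""Serialization: spike rasters and stimulus movies as CSV / HDF5."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .decoding import SpikeRaster
from .grid import MechanoreceptorGrid
from .stimulus import StimulusMovie


def save_raster_csv(raster: SpikeRaster, path) -> None:
    """Two-column (unit_id, time_ms) event list."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id", "time_ms"])
        for u, t in zip(raster.units, raster.times_ms):
            writer.writerow([int(u), float(t)])


def load_raster_csv(path, n_units: int, duration_ms: float) -> SpikeRaster:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        return SpikeRaster(np.array([], int), np.array([]), n_units, duration_ms)
    order = np.argsort(data[:, 1], kind="stable")
    return SpikeRaster(data[order, 0].astype(int), data[order, 1], n_units, duration_ms)


def save_raster_h5(raster: SpikeRaster, path, name: str = "raster") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("unit_id", data=raster.units.astype(np.int32))
        g.create_dataset("time_ms", data=raster.times_ms.astype(np.float64))
        g.attrs["n_units"] = raster.n_units
        g.attrs["duration_ms"] = raster.duration_ms
        for k, v in raster.meta.items():
            try:
                g.attrs[f"meta_{k}"] = v
            except TypeError:
                g.attrs[f"meta_{k}"] = str(v)


def load_raster_h5(path, name: str = "raster") -> SpikeRaster:
    with h5py.File(path, "r") as fh:
        g = fh[name]
        meta = {
            k[len("meta_"):]: g.attrs[k] for k in g.attrs if k.startswith("meta_")
        }
        return SpikeRaster(
            np.asarray(g["unit_id"]),
            np.asarray(g["time_ms"]),
            int(g.attrs["n_units"]),
            float(g.attrs["duration_ms"]),
            meta,
        )


def save_movie_h5(movie: StimulusMovie, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=movie.frames, compression="gzip")
        fh.create_dataset("time_ms", data=movie.times_ms)
        fh.attrs["dt_ms"] = movie.dt_ms
        fh.attrs["n_rows"] = movie.grid.n_rows
        fh.attrs["n_cols"] = movie.grid.n_cols
        fh.attrs["pitch_mm"] = movie.grid.pitch_mm
        for k, v in movie.meta.items():
            try:
                fh.attrs[f"meta_{k}"] = v
            except TypeError:
                fh.attrs[f"meta_{k}"] = str(v)


def load_movie_h5(path) -> StimulusMovie:
    with h5py.File(path, "r") as fh:
        grid = MechanoreceptorGrid(
            int(fh.attrs["n_rows"]), int(fh.attrs["n_cols"]), float(fh.attrs["pitch_mm"])
        )
        meta = {k[len("meta_"):]: fh.attrs[k] for k in fh.attrs if k.startswith("meta_")}
        return StimulusMovie(float(fh.attrs["dt_ms"]), np.asarray(fh["frames"]), grid, meta)


def save_movie_csv(movie: StimulusMovie, path, every_ms: float = 10.0) -> None:
    """Down-sampled frames for quick inspection (one row per kept frame)."""
    step = max(int(round(every_ms / movie.dt_ms)), 1)
    sub = movie.frames[::step]
    times = movie.times_ms[::step]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_ms"] + [f"site_{i}" for i in range(sub.shape[1])])
        for t, row in zip(times, sub):
            writer.writerow([float(t)] + [float(v) for v in row])
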