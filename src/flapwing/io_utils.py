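"""Field export (legacy VTK ASCII), CSV time series and HDF5 checkpoints."""

from __future__ import annotations

import json

import h5py
import numpy as np

__all__ = ["write_vtk", "save_checkpoint", "load_checkpoint"]


def write_vtk(path, origin, dx, scalars=None, vectors=None, title="flapwing fields"):
    """Legacy-VTK structured-points file with point data.

    ``scalars``: mapping name -> (nx, ny, nz) array; ``vectors``: mapping
    name -> (nx, ny, nz, 3) array.  ASCII, little numbers, external viewers
    do the rendering.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    arr = next(iter(scalars.values()), None)
    if arr is None:
        arr = next(iter(vectors.values()))[..., 0]
    nx, ny, nz = arr.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {dx} {dx} {dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, data in scalars.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, data.transpose(2, 1, 0).ravel()[:, None], fmt="%.9g")
        for name, data in vectors.items():
            fh.write(f"VECTORS {name} double\n")
            flat = data.transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.9g")


def save_checkpoint(path, sim, config_dict=None):
    """Write every block's full distribution state for exact restart."""
    with h5py.File(path, "w") as h5:
        h5.attrs["step_count"] = sim.step_count
        h5.attrs["dt_seconds"] = sim.dt_seconds
        if config_dict is not None:
            h5.attrs["config"] = json.dumps(config_dict)
        for i, b in enumerate(sim.blocks):
            g = h5.create_group(f"block{i}")
            g.create_dataset("f", data=b.f)
            g.attrs["time"] = b.time
            g.attrs["dx"] = b.dx
            g.attrs["origin"] = b.origin


def load_checkpoint(path, sim):
    """Restore a simulation saved with :func:`save_checkpoint` (in place)."""
    with h5py.File(path, "r") as h5:
        sim.step_count = int(h5.attrs["step_count"])
        for i, b in enumerate(sim.blocks):
            g = h5[f"block{i}"]
            b.f[:] = g["f"][:]
            b.time = float(g.attrs["time"])
    return sim
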