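"""HDF5 trajectory store.

Layout: datasets /phi /U /V /W (T x ny x nx, float32), /centroid (T x 2, um),
/time (s), /wstar, /area; the full flat configuration and the seed are stored
as root attributes so a file is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .params import SimulationConfig
from .simulator import Trajectory

__all__ = ["save_trajectory", "load_trajectory"]


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=traj.times)
        fh.create_dataset("phi", data=traj.phi, compression="gzip", compression_opts=4)
        for name in ("U", "V", "W"):
            data = getattr(traj, name)
            if data is not None:
                fh.create_dataset(name, data=data, compression="gzip", compression_opts=4)
        fh.create_dataset("centroid", data=traj.centroid)
        fh.create_dataset("wstar", data=traj.wstar)
        fh.create_dataset("area", data=traj.area)
        if traj.config is not None:
            for key, value in traj.config.to_flat_dict().items():
                fh.attrs[key] = value
        if traj.seed is not None:
            fh.attrs["seed"] = traj.seed
        fh.attrs["extinct"] = traj.extinct
        fh.attrs["fragmentation_events"] = json.dumps(traj.fragmentation_events)


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        attrs = dict(fh.attrs)
        seed = int(attrs.pop("seed", 0))
        extinct = bool(attrs.pop("extinct", False))
        frag = json.loads(str(attrs.pop("fragmentation_events", "[]")))
        config = SimulationConfig.from_flat_dict(
            {k: (v.item() if isinstance(v, np.generic) else v) for k, v in attrs.items()}
        )
        return Trajectory(
            times=fh["time"][:],
            phi=fh["phi"][:],
            U=fh["U"][:] if "U" in fh else None,
            V=fh["V"][:] if "V" in fh else None,
            W=fh["W"][:] if "W" in fh else None,
            centroid=fh["centroid"][:],
            wstar=fh["wstar"][:],
            area=fh["area"][:],
            fragmentation_events=frag,
            config=config,
            seed=seed,
            extinct=extinct,
        )
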