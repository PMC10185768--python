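"""HDF5 and CSV persistence for recordings, forward models and tables.

Container layout (one HDF5 file per recording):

- ``/eit/pair_<k>``      (14, n) float32 electrode-voltage traces, volts
- ``/eit/baseline``      (196,) baseline transfer voltages
- ``/physio/<name>``     auxiliary channels (bp, etco2, ecg, emg)
- ``/triggers``          event times, seconds
- ``/forward/J``         voxel Jacobian (196, n_voxels)
- ``/forward/voxel_centers``  (n_voxels, 2) meters

Root attributes carry sampling/carrier rates and protocol metadata.
Tables (fascicles, stimulation responses, CoMs) are CSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import coregister as cg
from .forward import JacobianMatrix, VoxelGrid
from .geometry import N_ELECTRODES, PROTOCOL_SKIP
from .phantom import PhysioSignals
from .sigproc import TriggerSeries


def write_recording(path: str | Path, recording, physio: PhysioSignals | None = None,
                    compress: bool = True) -> Path:
    """Materialize a recording (lazy or stored) into the HDF5 container."""
    path = Path(path)
    opts = dict(compression="gzip", compression_opts=4) if compress else {}
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["carrier_frequency"] = recording.carrier_frequency
        f.attrs["carrier_amplitude"] = recording.carrier_amplitude
        f.attrs["electrode_count"] = recording.electrode_count
        f.attrs["skip"] = recording.skip
        f.attrs["n_samples"] = recording.n_samples
        g = f.create_group("eit")
        for k in range(len(recording.injection_pairs)):
            g.create_dataset(f"pair_{k}", data=recording.pair_traces(k),
                             dtype="f4", **opts)
        g.create_dataset("baseline", data=recording.baseline_voltages)
        g.create_dataset("injection_pairs",
                         data=np.asarray(recording.injection_pairs))
        if recording.trigger_times is not None:
            f.create_dataset("triggers", data=recording.trigger_times)
        physio = physio or recording.physio
        if physio is not None:
            pgrp = f.create_group("physio")
            pgrp.attrs["sampling_rate"] = physio.sampling_rate
            pgrp.attrs["heart_rate"] = physio.heart_rate
            pgrp.attrs["breath_rate"] = physio.breath_rate
            for name in ("bp", "etco2", "ecg", "emg"):
                pgrp.create_dataset(name, data=getattr(physio, name),
                                    dtype="f4", **opts)
            pgrp.create_dataset("beat_times", data=physio.beat_times)
            pgrp.create_dataset("breath_midpoints", data=physio.breath_midpoints)
    return path


class StoredRecording:
    """Read-side counterpart of a raw recording; pair traces load on demand."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with h5py.File(self.path, "r") as f:
            self.sampling_rate = float(f.attrs["sampling_rate"])
            self.carrier_frequency = float(f.attrs["carrier_frequency"])
            self.carrier_amplitude = float(f.attrs["carrier_amplitude"])
            self.electrode_count = int(f.attrs["electrode_count"])
            self.skip = int(f.attrs["skip"])
            self.n_samples = int(f.attrs["n_samples"])
            self.injection_pairs = [tuple(p) for p in f["eit/injection_pairs"][()]]
            self.baseline_voltages = f["eit/baseline"][()]
            self.trigger_times = f["triggers"][()] if "triggers" in f else None
            self.physio = None
            if "physio" in f:
                p = f["physio"]
                self.physio = PhysioSignals(
                    sampling_rate=float(p.attrs["sampling_rate"]),
                    bp=p["bp"][()].astype(float),
                    etco2=p["etco2"][()].astype(float),
                    ecg=p["ecg"][()].astype(float),
                    emg=p["emg"][()].astype(float),
                    heart_rate=float(p.attrs["heart_rate"]),
                    breath_rate=float(p.attrs["breath_rate"]),
                    beat_times=p["beat_times"][()],
                    breath_midpoints=p["breath_midpoints"][()],
                )

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def pair_traces(self, k: int) -> np.ndarray:
        with h5py.File(self.path, "r") as f:
            return f[f"eit/pair_{k}"][()].astype(float)


def write_forward(path: str | Path, jacobian: JacobianMatrix,
                  baseline_voltages: np.ndarray) -> Path:
    path = Path(path)
    with h5py.File(path, "a") as f:
        if "forward" in f:
            del f["forward"]
        g = f.create_group("forward")
        g.create_dataset("J", data=jacobian.matrix)
        g.create_dataset("voxel_centers", data=jacobian.grid.centers)
        g.create_dataset("voxel_empty", data=jacobian.grid.empty)
        g.attrs["voxel_size"] = jacobian.grid.voxel_size
        g.attrs["nerve_radius"] = jacobian.grid.nerve_radius
        g.create_dataset("baseline", data=baseline_voltages)
    return path


def read_forward(path: str | Path) -> tuple[JacobianMatrix, np.ndarray]:
    with h5py.File(path, "r") as f:
        g = f["forward"]
        grid = VoxelGrid(voxel_size=float(g.attrs["voxel_size"]),
                         centers=g["voxel_centers"][()],
                         nerve_radius=float(g.attrs["nerve_radius"]),
                         empty=g["voxel_empty"][()])
        from .forward import measurement_table
        J = JacobianMatrix(matrix=g["J"][()],
                           index=measurement_table(N_ELECTRODES, PROTOCOL_SKIP),
                           grid=grid)
        return J, g["baseline"][()]


def write_fascicle_table(path: str | Path, table: cg.FascicleTable) -> Path:
    path = Path(path)
    df = table.table.copy()
    df.attrs = {}
    header = (f"# outline_ellipse cx={table.outline.cx} cy={table.outline.cy} "
              f"a={table.outline.a} b={table.outline.b} "
              f"phi_deg={table.outline.phi_deg} "
              f"cuff_opening_deg={table.cuff_opening_deg} "
              f"nerve_radius_um={table.nerve_radius_um}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_fascicle_table(path: str | Path) -> cg.FascicleTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split()
                if "=" in kv and not kv.startswith("outline"))
    outline = cg.EllipseOutline(cx=float(meta["cx"]), cy=float(meta["cy"]),
                                a=float(meta["a"]), b=float(meta["b"]),
                                phi_deg=float(meta["phi_deg"]))
    return cg.FascicleTable(table=df, outline=outline,
                            cuff_opening_deg=float(meta["cuff_opening_deg"]),
                            nerve_radius_um=float(meta["nerve_radius_um"]))


def write_triggers(path: str | Path, triggers: TriggerSeries) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": triggers.times,
                  "source": triggers.source}).to_csv(path, index=False)
    return path
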