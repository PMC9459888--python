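"""Array-container (HDF5), CSV and WAV persistence.

Trace stacks and labeled datasets round-trip bit-exactly through HDF5 files
with named datasets and provenance attributes; every file carries a schema
version that is checked on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .dataset import AcousticImage, LabeledExample
from .fiber import RayleighTraceSet

SCHEMA_VERSION = "1"

__all__ = ["save_traces", "load_traces", "save_dataset", "load_dataset", "export_wav"]


def _check_schema(f: h5py.File, path) -> None:
    found = f.attrs.get("schema_version")
    if found != SCHEMA_VERSION:
        raise IOError(f"{path}: schema version mismatch, expected {SCHEMA_VERSION!r}, found {found!r}")


def save_traces(path, traces: RayleighTraceSet) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "rayleigh_traces"
        f.attrs["seed"] = traces.seed
        f.attrs["provenance"] = json.dumps(traces.provenance)
        f.create_dataset("traces", data=traces.traces, compression="gzip", shuffle=True)
        f.create_dataset("distance_axis", data=traces.distance_axis)
        f.create_dataset("time_axis", data=traces.time_axis)


def load_traces(path) -> RayleighTraceSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        return RayleighTraceSet(
            traces=f["traces"][...],
            distance_axis=f["distance_axis"][...],
            time_axis=f["time_axis"][...],
            seed=int(f.attrs["seed"]),
            provenance=json.loads(f.attrs["provenance"]),
        )


def save_dataset(path, examples: list[LabeledExample], csv_twin: bool = True) -> None:
    """Persist labeled examples plus a CSV metadata twin for inspection."""
    path = Path(path)
    xt = np.stack([ex.temporal.matrix for ex in examples]).astype(np.float32)
    xs = np.stack([ex.spectral.matrix for ex in examples]).astype(np.float32)
    meta = pd.DataFrame({
        "tree_id": [ex.temporal.tree_id for ex in examples],
        "window_index": [ex.temporal.window_index for ex in examples],
        "label": [ex.label for ex in examples],
        "sublabel": [ex.sublabel for ex in examples],
        "snr_db": [ex.snr_db for ex in examples],
    })
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "labeled_dataset"
        f.create_dataset("temporal", data=xt, compression="gzip", shuffle=True)
        f.create_dataset("spectral", data=xs, compression="gzip", shuffle=True)
        for col in meta.columns:
            data = meta[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            f.create_dataset(f"meta/{col}", data=data)
    if csv_twin:
        meta.to_csv(path.with_suffix(".csv"), index=False)


def load_dataset(path) -> list[LabeledExample]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        xt = f["temporal"][...]
        xs = f["spectral"][...]
        tree_id = f["meta/tree_id"][...].astype(str)
        window_index = f["meta/window_index"][...]
        sublabel = f["meta/sublabel"][...].astype(str)
        snr = f["meta/snr_db"][...]
    return [
        LabeledExample(
            temporal=AcousticImage(xt[i], tree_id[i], int(window_index[i]), "temporal"),
            spectral=AcousticImage(xs[i], tree_id[i], int(window_index[i]), "spectral"),
            sublabel=sublabel[i],
            snr_db=float(snr[i]),
        )
        for i in range(xt.shape[0])
    ]


def export_wav(path, values: np.ndarray, sample_rate: float = 5000.0) -> None:
    """Write one bin's acoustic series as 16-bit PCM for auditioning."""
    x = np.asarray(values, dtype=np.float64)
    peak = float(np.max(np.abs(x))) or 1.0
    pcm = np.clip(x / peak * 32767.0, -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), int(round(sample_rate)), pcm)
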