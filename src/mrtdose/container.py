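"""HDF5 dataset container for simulated dose samples.

Layout::

    /samples/<id>/density       (96,16,16) float32, g/cm^3
    /samples/<id>/materials     (96,16,16) int8 labels
    /samples/<id>/tumor_mask    (96,16,16) bool
    /samples/<id>/peak_mean     (96,16,16) float32
    /samples/<id>/peak_se       (96,16,16) float32
    /samples/<id>/valley_mean   (96,16,16) float32
    /samples/<id>/valley_se     (96,16,16) float32
    [/samples/<id>/peak_pred, valley_pred]   written back by the engine

Root attributes record voxel size, beam configuration, noise regime, seeds
and the config hash; per-sample attributes record provenance (base phantom,
partition, transform, per-sample seed).  Datasets are written with HDF5
object timestamps disabled so identical runs produce bitwise-identical
files.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

_DTYPES = {
    "density": np.float32,
    "materials": np.int8,
    "tumor_mask": bool,
    "peak_mean": np.float32,
    "peak_se": np.float32,
    "valley_mean": np.float32,
    "valley_se": np.float32,
    "peak_truth": np.float32,
    "valley_truth": np.float32,
    "peak_pred": np.float32,
    "valley_pred": np.float32,
}


def _write_array(group: h5py.Group, name: str, data: np.ndarray) -> None:
    if name in group:
        del group[name]
    group.create_dataset(name, data=np.asarray(data, dtype=_DTYPES.get(name)), track_times=False)


class DoseDataset:
    """Thin reader/writer around the HDF5 sample container."""

    def __init__(self, path: str, mode: str = "r"):
        self.path = str(path)
        self._file = h5py.File(self.path, mode, track_order=True)
        if "samples" not in self._file and mode in ("w", "a", "r+"):
            self._file.create_group("samples")

    # -- context manager -------------------------------------------------
    def __enter__(self) -> "DoseDataset":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._file.close()

    # -- attributes ------------------------------------------------------
    def set_metadata(self, **attrs) -> None:
        for key, val in attrs.items():
            if isinstance(val, (dict, list, tuple)):
                val = json.dumps(val, sort_keys=True)
            self._file.attrs[key] = val

    def metadata(self) -> dict:
        out = {}
        for key, val in self._file.attrs.items():
            if isinstance(val, (bytes, str)):
                try:
                    out[key] = json.loads(val)
                    continue
                except (json.JSONDecodeError, TypeError):
                    pass
            out[key] = val
        return out

    # -- samples ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self._file["samples"].keys())

    def write_sample(self, sample_id: str, arrays: dict[str, np.ndarray], attrs: dict | None = None) -> None:
        samples = self._file["samples"]
        grp = samples.require_group(sample_id)
        for name, data in arrays.items():
            _write_array(grp, name, data)
        for key, val in (attrs or {}).items():
            if isinstance(val, (dict, list, tuple)):
                val = json.dumps(val, sort_keys=True)
            grp.attrs[key] = val

    def read_sample(self, sample_id: str) -> dict[str, np.ndarray]:
        grp = self._file["samples"][sample_id]
        return {name: grp[name][()] for name in grp}

    def sample_attrs(self, sample_id: str) -> dict:
        grp = self._file["samples"][sample_id]
        out = {}
        for key, val in grp.attrs.items():
            if isinstance(val, (bytes, str)):
                try:
                    out[key] = json.loads(val)
                    continue
                except (json.JSONDecodeError, TypeError):
                    pass
            out[key] = val
        return out

    def partition_ids(self, partition: str) -> list[str]:
        return [
            sid for sid in self.sample_ids
            if self.sample_attrs(sid).get("partition") == partition
        ]
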