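"""Serialization: HDF5 epoch and fragility stores, EDF import, TSV export.

Epoch store layout (HDF5)::

    /data          float64, M x N (microvolts)
    /electrodes    M variable-length UTF-8 strings
    /row_data/<col>   one dataset per per-electrode column
    /meta_data     group; each value a JSON-encoded scalar attribute
    attrs: start_time (s, onset = 0), sampling_rate (Hz)

Writes are atomic (temp file + rename).  EDF import goes through ``mne``.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .epoch import Epoch
from .fragility import FragilityResults

__all__ = [
    "write_epoch", "read_epoch", "import_edf",
    "write_fragility", "read_fragility",
]


def _atomic_h5(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            writer(f)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_STR = h5py.string_dtype(encoding="utf-8")


def write_epoch(epoch: Epoch, path) -> None:
    """Write an :class:`Epoch` to the HDF5 store (atomic overwrite)."""

    def writer(f: h5py.File) -> None:
        f.create_dataset("data", data=np.asarray(epoch.data, dtype=np.float64))
        f.create_dataset("electrodes", data=np.array(epoch.electrodes, dtype=object),
                         dtype=_STR)
        f.attrs["start_time"] = float(epoch.start_time)
        f.attrs["sampling_rate"] = float(epoch.sampling_rate)
        rg = f.create_group("row_data")
        rg.attrs["column_order"] = json.dumps(list(map(str, epoch.row_data.columns)))
        for col in epoch.row_data.columns:
            vals = epoch.row_data[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                rg.create_dataset(str(col), data=vals.astype(object), dtype=_STR)
            else:
                rg.create_dataset(str(col), data=vals)
        mg = f.create_group("meta_data")
        for key, val in epoch.meta_data.items():
            mg.attrs[str(key)] = json.dumps(val)

    _atomic_h5(Path(path), writer)


def read_epoch(path) -> Epoch:
    """Read and validate an :class:`Epoch` from the HDF5 store."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for member in ("data", "electrodes"):
            if member not in f:
                raise KeyError(f"{path}: missing required dataset '/{member}'")
        for attr in ("start_time", "sampling_rate"):
            if attr not in f.attrs:
                raise KeyError(f"{path}: missing required attribute '{attr}'")
        data = f["data"][()].astype(np.float64)
        electrodes = [e.decode() if isinstance(e, bytes) else str(e)
                      for e in f["electrodes"][()]]
        start_time = float(f.attrs["start_time"])
        rate = float(f.attrs["sampling_rate"])
        row_data = None
        if "row_data" in f:
            rg = f["row_data"]
            order = json.loads(rg.attrs.get("column_order", "null")) or sorted(rg.keys())
            cols = {}
            for col in order:
                vals = rg[col][()]
                if vals.dtype.kind in "OS":
                    vals = np.array([v.decode() if isinstance(v, bytes) else v
                                     for v in vals], dtype=object)
                cols[col] = vals
            row_data = pd.DataFrame(cols, index=range(data.shape[0]))
        meta = {}
        if "meta_data" in f:
            for key, val in f["meta_data"].attrs.items():
                meta[key] = json.loads(val)
    return Epoch(data=data, electrodes=electrodes, start_time=start_time,
                 sampling_rate=rate, row_data=row_data, meta_data=meta)


def import_edf(path, channel_include: Sequence[str] | None = None,
               start_time: float = 0.0,
               allow_mixed_rates: bool = False) -> Epoch:
    """Read an EDF/EDF+ recording into an :class:`Epoch` (via ``mne``).

    Voltages are converted to microvolts; ``start_time`` anchors the first
    sample relative to seizure onset (default 0, i.e. onset unknown).
    Files with mixed per-channel sampling rates are rejected unless
    ``allow_mixed_rates=True``, in which case every channel is resampled on
    import to the highest rate in the file.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    extras = (raw._raw_extras or [{}])[0]
    n_samps = np.asarray(extras.get("n_samps", []))
    if not allow_mixed_rates and n_samps.size and np.unique(n_samps).size > 1:
        raise ValueError(
            f"{path}: channels have mixed sampling rates; pass "
            "allow_mixed_rates=True to resample all channels to the highest rate"
        )
    if channel_include is not None:
        missing = [c for c in channel_include if c not in raw.ch_names]
        if missing:
            raise KeyError(f"channel(s) not in EDF: {missing}")
        raw.pick(list(channel_include))
    data = raw.get_data() * 1e6  # Volts -> microvolts
    return Epoch(
        data=data,
        electrodes=list(raw.ch_names),
        start_time=float(start_time),
        sampling_rate=float(raw.info["sfreq"]),
        meta_data={"source": str(path)},
    )


def write_fragility(frag: FragilityResults, path, format: str = "h5") -> None:
    """Write fragility results as HDF5 (full object) or TSV (matrix only).

    The TSV has electrode rows and window-start-time columns at 6
    significant digits.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(frag.fragility, index=frag.electrodes,
                          columns=[f"{t:.6g}" for t in frag.window_starts])
        df.index.name = "electrode"
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", float_format="%.6g")
        return
    if format != "h5":
        raise ValueError(f"format must be 'h5' or 'tsv', got {format!r}")

    def writer(f: h5py.File) -> None:
        f.create_dataset("fragility", data=frag.fragility)
        f.create_dataset("raw_norms", data=frag.raw_norms)
        f.create_dataset("window_starts", data=frag.window_starts)
        f.create_dataset("lambdas", data=frag.lambdas)
        f.create_dataset("stable_flags", data=frag.stable_flags.astype(np.int8))
        f.create_dataset("electrodes", data=np.array(frag.electrodes, dtype=object),
                         dtype=_STR)
        if frag.soz_mask is not None:
            f.create_dataset("soz_mask", data=frag.soz_mask.astype(np.int8))
        f.attrs["window_size"] = frag.window_size
        f.attrs["step"] = frag.step
        f.attrs["omega_grid_size"] = frag.omega_grid_size
        f.attrs["structure"] = frag.structure
        f.attrs["sampling_rate"] = frag.sampling_rate
        f.attrs["normalize"] = frag.normalize
        f.attrs["params"] = json.dumps(frag.params)

    _atomic_h5(path, writer)


def read_fragility(path) -> FragilityResults:
    """Read a :class:`FragilityResults` back from its HDF5 store."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for member in ("fragility", "raw_norms", "window_starts", "lambdas",
                       "stable_flags", "electrodes"):
            if member not in f:
                raise KeyError(f"{path}: missing required dataset '/{member}'")
        soz = f["soz_mask"][()].astype(bool) if "soz_mask" in f else None
        return FragilityResults(
            fragility=f["fragility"][()],
            raw_norms=f["raw_norms"][()],
            window_starts=f["window_starts"][()],
            window_size=int(f.attrs["window_size"]),
            step=int(f.attrs["step"]),
            lambdas=f["lambdas"][()],
            stable_flags=f["stable_flags"][()].astype(bool),
            electrodes=[e.decode() if isinstance(e, bytes) else str(e)
                        for e in f["electrodes"][()]],
            omega_grid_size=int(f.attrs["omega_grid_size"]),
            structure=str(f.attrs["structure"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            normalize=str(f.attrs["normalize"]),
            soz_mask=soz,
            params=json.loads(f.attrs["params"]),
        )
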