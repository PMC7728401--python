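"""Readers and writers for traces, stimulus specifications, fitted models
and decomposition tables.

Conventions: traces are neurons-as-rows (N x T); frame indexing is 0-based
everywhere; onset tables give the first frame at/after stimulus onset.
Auto-transposing a traces file is refused — pass ``transpose=True``
explicitly if the file is frames-as-rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CalciumKernel, CilvaModel, FluorescenceMatrix, StimulusDesign

__all__ = [
    "read_traces",
    "write_traces",
    "read_stimulus",
    "write_stimulus",
    "save_model",
    "load_model",
    "write_metrics_table",
    "write_components",
    "write_manifest",
]

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def _sniff_delimiter(path: Path) -> str | None:
    """Pick the delimiter from the first line; None means whitespace."""
    first = path.open().readline()
    counts = {d: first.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else None

def _read_numeric_table(path: Path) -> np.ndarray:
    """Delimited numeric text, optional single header row, NaN-rejecting.

    Parsed with round-trip float precision so that writing with %.17g and
    reading back is bit-exact.
    """
    delim = _sniff_delimiter(path)
    kw = dict(header=None, float_precision="round_trip")
    kw["sep"] = delim if delim is not None else r"\s+"
    df = pd.read_csv(path, **kw)
    # a non-numeric first row is treated as a header
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = pd.read_csv(path, header=0, float_precision="round_trip",
                         sep=kw["sep"])
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(f"{path}: NaN entry at (row {r}, col {c})")
    return arr


def read_traces(
    path: str | Path,
    fs: float,
    dataset: str = "F",
    transpose: bool = False,
) -> FluorescenceMatrix:
    """Read an N x T fluorescence matrix from delimited text or HDF5.

    ``fs`` (Hz) must be supplied; HDF5 files are read from ``dataset``.
    """
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as h5:
            if dataset not in h5:
                raise KeyError(f"{path}: no dataset named '{dataset}'")
            arr = np.asarray(h5[dataset], dtype=float)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(f"{path}: NaN entry at (row {r}, col {c})")
    else:
        arr = _read_numeric_table(path)
    if transpose:
        arr = arr.T
    return FluorescenceMatrix(arr, fs=fs)


def write_traces(path: str | Path, F: FluorescenceMatrix) -> None:
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("F", data=F.values)
            h5.attrs["fs"] = F.fs
    else:
        np.savetxt(path, F.values, delimiter=",", fmt="%.17g")


def read_stimulus(
    path: str | Path,
    T: int,
    K_hint: int | None = None,
    shift_count: int = 0,
) -> StimulusDesign:
    """Read a stimulus specification: binary K x T matrix or onset table.

    A two-column file is interpreted as an onset table (frame, stimulus id);
    anything else must be a binary matrix with T columns.  Duplicate
    (frame, stimulus) pairs collapse to a single onset with a warning;
    out-of-range onsets are an error.
    """
    import warnings

    arr = _read_numeric_table(Path(path))
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape[1] != T:
        frames = arr[:, 0].astype(int)
        stims = arr[:, 1].astype(int)
        if np.any((frames < 0) | (frames >= T)):
            raise ValueError("onset frame outside [0, T)")
        if np.any(stims < 0):
            raise ValueError("negative stimulus index")
        K = K_hint if K_hint is not None else int(stims.max()) + 1
        if np.any(stims >= K):
            raise ValueError(f"stimulus index exceeds K={K}")
        S = np.zeros((K, T))
        if len(set(zip(frames.tolist(), stims.tolist()))) < len(frames):
            warnings.warn("duplicate (frame, stimulus) onsets collapsed")
        S[stims, frames] = 1.0
        design = StimulusDesign(S)
    else:
        if arr.shape[1] != T:
            raise ValueError(f"stimulus matrix has {arr.shape[1]} columns, expected T={T}")
        design = StimulusDesign(arr)  # binary contract enforced by the type
    if shift_count:
        design = design.with_shifted_copies(shift_count)
    return design


def write_stimulus(path: str | Path, S: StimulusDesign) -> None:
    np.savetxt(path, S.matrix, delimiter=",", fmt="%d")


def save_model(path: str | Path, model: CilvaModel) -> None:
    with h5py.File(path, "w") as h5:
        for name in ("alpha", "beta", "W", "B", "X", "sigma2"):
            h5.create_dataset(name, data=getattr(model, name))
        h5.attrs["gamma"] = model.gamma
        g = h5.create_group("kernel")
        g.create_dataset("values", data=model.kernel.values)
        g.attrs["tau_r"] = model.kernel.tau_r
        g.attrs["tau_d"] = model.kernel.tau_d
        g.attrs["truncation_tol"] = model.kernel.truncation_tol
        h5.create_dataset("fit_history", data=np.asarray(model.fit_history))


def load_model(path: str | Path) -> CilvaModel:
    with h5py.File(path, "r") as h5:
        kernel = CalciumKernel(
            tau_r=float(h5["kernel"].attrs["tau_r"]),
            tau_d=float(h5["kernel"].attrs["tau_d"]),
            values=np.asarray(h5["kernel/values"]),
            truncation_tol=float(h5["kernel"].attrs["truncation_tol"]),
        )
        model = CilvaModel(
            alpha=np.asarray(h5["alpha"]), beta=np.asarray(h5["beta"]),
            W=np.asarray(h5["W"]), B=np.asarray(h5["B"]), X=np.asarray(h5["X"]),
            sigma2=np.asarray(h5["sigma2"]), gamma=float(h5.attrs["gamma"]),
            kernel=kernel, fit_history=list(np.asarray(h5["fit_history"])),
        )
    return model


def write_metrics_table(path: str | Path, decomp, neuron_ids=None) -> None:
    """Per-neuron metric table as CSV."""
    N = len(decomp.var_evoked)
    df = pd.DataFrame({
        "neuron": neuron_ids if neuron_ids is not None else np.arange(N),
        "var_evoked": decomp.var_evoked,
        "var_spont": decomp.var_spont,
        "cov_es": decomp.cov_es,
        "drive_ratio": decomp.drive_ratio,
        "var_corrected": decomp.var_corrected,
        "private_var": decomp.private_var,
        "private_negative": decomp.private_negative,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def write_components(path: str | Path, decomp) -> None:
    """Trace components (evoked, spontaneous, residual) as HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("f_evoked", data=decomp.f_evoked)
        h5.create_dataset("f_spont", data=decomp.f_spont)
        if decomp.residual is not None:
            h5.create_dataset("residual", data=decomp.residual)
        h5.create_dataset("contribution_index", data=decomp.contribution_index)


def write_manifest(path: str | Path, **fields) -> None:
    """Machine-readable run manifest (config, seeds, objective trace, versions)."""
    import cilva

    manifest = {"cilva_version": cilva.__version__, "numpy_version": np.__version__}
    manifest.update(fields)
    Path(path).write_text(json.dumps(manifest, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
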