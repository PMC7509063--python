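"""Dataset readers and writers (HDF5, NPZ, MAT).

Axis convention throughout: channels x samples per trial; the full dataset
array is (subjects, classes, trials, channels, samples).

HDF5 layout::

    /subject_<p>/class_<i>/trial_<h>   float dataset, channels x samples
    root attrs: fs, frequencies, phases, lapse_flags (S x K x N bool)

MAT epoch archives are read through :func:`load_mat`, which expects a single
4-D variable (default name ``eeg``) holding one subject's epochs; the axis
order is declared by the caller as a permutation string over
``c`` (channels), ``s`` (samples), ``k`` (classes), ``t`` (trials) — e.g.
``"kcst"`` for arrays stored as (class, channel, sample, trial).
"""

from __future__ import annotations

import logging

import h5py
import numpy as np
import scipy.io

from .signal_models import Dataset, StimulusConfig

logger = logging.getLogger(__name__)

__all__ = ["DataFormatError", "save_hdf5", "load_hdf5", "save_npz",
           "load_npz", "load_mat", "load_dataset"]


class DataFormatError(ValueError):
    """A dataset file is malformed or missing required metadata."""


def save_hdf5(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = dataset.fs
        f.attrs["frequencies"] = np.asarray(dataset.stim.frequencies)
        if dataset.stim.phases is not None:
            f.attrs["phases"] = np.asarray(dataset.stim.phases)
        f.create_dataset("lapse_flags", data=dataset.lapse_flags)
        for p in range(dataset.n_subjects):
            for i in range(dataset.n_classes):
                g = f.require_group(f"subject_{p}/class_{i}")
                for h in range(dataset.n_trials):
                    g.create_dataset(f"trial_{h}", data=dataset.data[p, i, h])


def load_hdf5(path) -> Dataset:
    try:
        with h5py.File(path, "r") as f:
            if "fs" not in f.attrs:
                raise DataFormatError("missing required attribute 'fs'")
            if "frequencies" not in f.attrs:
                raise DataFormatError("missing required attribute 'frequencies'")
            fs = float(f.attrs["fs"])
            freqs = tuple(np.asarray(f.attrs["frequencies"], dtype=float))
            phases = tuple(np.asarray(f.attrs["phases"], dtype=float)) \
                if "phases" in f.attrs else None
            subjects = sorted((k for k in f if k.startswith("subject_")),
                              key=lambda k: int(k.split("_")[1]))
            if not subjects:
                raise DataFormatError("no subject groups found")
            data = []
            for sk in subjects:
                classes = sorted(f[sk], key=lambda k: int(k.split("_")[1]))
                if len(classes) != len(freqs):
                    raise DataFormatError(
                        f"{sk}: {len(classes)} class groups but "
                        f"{len(freqs)} frequencies")
                subj = []
                for ck in classes:
                    trials = sorted(f[sk][ck],
                                    key=lambda k: int(k.split("_")[1]))
                    subj.append([f[sk][ck][tk][()] for tk in trials])
                data.append(subj)
            data = np.asarray(data, dtype=float)
            lapse = f["lapse_flags"][()] if "lapse_flags" in f else None
    except OSError as e:
        raise DataFormatError(f"cannot read HDF5 file {path}: {e}") from e
    stim = StimulusConfig(freqs, phases)
    return Dataset(data, fs=fs, stim=stim, lapse_flags=lapse)


def save_npz(dataset: Dataset, path) -> None:
    np.savez(path, data=dataset.data, fs=dataset.fs,
             frequencies=np.asarray(dataset.stim.frequencies),
             phases=(np.asarray(dataset.stim.phases)
                     if dataset.stim.phases is not None else np.array([])),
             lapse_flags=dataset.lapse_flags)


def load_npz(path) -> Dataset:
    try:
        with np.load(path) as z:
            for key in ("data", "fs", "frequencies"):
                if key not in z:
                    raise DataFormatError(f"missing required field {key!r}")
            data = z["data"]
            fs = float(z["fs"])
            freqs = tuple(z["frequencies"].astype(float))
            phases = tuple(z["phases"].astype(float)) if z["phases"].size else None
            lapse = z["lapse_flags"] if "lapse_flags" in z else None
    except (OSError, ValueError) as e:
        if isinstance(e, DataFormatError):
            raise
        raise DataFormatError(f"cannot read NPZ file {path}: {e}") from e
    return Dataset(data, fs=fs, stim=StimulusConfig(freqs, phases),
                   lapse_flags=lapse)


def load_mat(path, stim: StimulusConfig, fs: float, var_name: str = "eeg",
             axes: str = "kcst") -> Dataset:
    """Load one subject's MAT epoch archive as a single-subject Dataset.

    ``axes`` declares the stored axis order using the letters
    k (class), c (channel), s (sample), t (trial).
    """
    if sorted(axes) != ["c", "k", "s", "t"]:
        raise DataFormatError("axes must be a permutation of 'kcst'")
    try:
        mat = scipy.io.loadmat(path)
    except (OSError, ValueError) as e:
        raise DataFormatError(f"cannot read MAT file {path}: {e}") from e
    if var_name not in mat:
        raise DataFormatError(
            f"variable {var_name!r} not found; file has "
            f"{[k for k in mat if not k.startswith('__')]}")
    arr = np.asarray(mat[var_name], dtype=float)
    if arr.ndim != 4:
        raise DataFormatError(f"variable {var_name!r} must be 4-D, "
                              f"got shape {arr.shape}")
    perm = [axes.index(a) for a in "kcst"]
    arr = np.transpose(arr, perm)  # -> class, channel, sample, trial
    arr = np.moveaxis(arr, -1, 1)  # -> class, trial, channel, sample
    if arr.shape[0] != stim.K:
        raise DataFormatError(
            f"class axis has {arr.shape[0]} entries, stimulus table has {stim.K}")
    return Dataset(arr[None], fs=fs, stim=stim)


def load_dataset(path, format: str | None = None, **kwargs) -> Dataset:
    """Dispatch loader; format inferred from the suffix when omitted."""
    if format is None:
        s = str(path)
        if s.endswith((".h5", ".hdf5")):
            format = "hdf5"
        elif s.endswith(".npz"):
            format = "npz"
        elif s.endswith(".mat"):
            format = "mat"
        else:
            raise DataFormatError(f"cannot infer format of {path}")
    if format == "hdf5":
        return load_hdf5(path)
    if format == "npz":
        return load_npz(path)
    if format == "mat":
        return load_mat(path, **kwargs)
    raise DataFormatError(f"unknown format {format!r}")
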