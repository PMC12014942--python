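"""File formats: HDF5 / NPZ / multi-page TIFF containers for fringe stacks,
MTF stacks and parameter maps, with channel-order metadata and atomic
writes."""
from __future__ import annotations

import hashlib
import json
import os
import tempfile

import numpy as np

from .demodulation import MTFStack, PhaseTriplet
from .inversion import ParameterMaps
from .optics import AcquisitionGeometry, InvalidInputError, PARAM_NAMES, PARAM_UNITS

__all__ = ["read_stack", "write_mtf", "read_mtf", "write_params",
           "read_params", "write_pair", "read_pair", "write_series",
           "read_series"]


def _atomic_path(path, suffix=".tmp"):
    # keep the real extension on the temp file: numpy's savez appends .npz
    # to paths that lack it, which would break the final rename
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=suffix)
    os.close(fd)
    return tmp


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# MTF stacks and parameter maps
# ---------------------------------------------------------------------------

def write_mtf(path: str, mtf: MTFStack, seed=None, extra_attrs=None):
    """Write an MTF stack to .h5 or .npz with channel-order metadata."""
    if str(path).endswith(".npz"):
        tmp = _atomic_path(path, suffix=".npz")
        np.savez(tmp, mtf=mtf.data,
                 wavelengths=np.asarray(mtf.wavelengths),
                 idc0=np.asarray(mtf.idc0), iac0=np.asarray(mtf.iac0),
                 channel_names=np.array(mtf.channel_names))
        os.replace(tmp, path)
        return
    import h5py
    tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as f:
        d = f.create_dataset("mtf", data=mtf.data)
        d.attrs["channel_names"] = list(mtf.channel_names)
        d.attrs["wavelengths_nm"] = list(mtf.wavelengths)
        d.attrs["idc0"] = list(mtf.idc0)
        d.attrs["iac0"] = list(mtf.iac0)
        if seed is not None:
            f.attrs["seed"] = seed
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v
    os.replace(tmp, path)


def read_mtf(path: str) -> MTFStack:
    if str(path).endswith(".npz"):
        with np.load(path) as z:
            return MTFStack(z["mtf"], wavelengths=tuple(z["wavelengths"]),
                            idc0=tuple(z["idc0"]), iac0=tuple(z["iac0"]))
    import h5py
    with h5py.File(path, "r") as f:
        if "mtf" not in f:
            raise InvalidInputError(
                f"{path}: expected a dataset 'mtf' of shape (n, m, 6)")
        d = f["mtf"]
        return MTFStack(d[...],
                        wavelengths=tuple(d.attrs.get("wavelengths_nm",
                                                      (623, 540, 460))),
                        idc0=tuple(d.attrs.get("idc0", (1, 1, 1))),
                        iac0=tuple(d.attrs.get("iac0", (1, 1, 1))))


def write_params(path: str, maps: ParameterMaps, seed=None):
    """Write parameter maps to .h5 (with names/units attrs) or .npz."""
    if str(path).endswith(".npz"):
        tmp = _atomic_path(path, suffix=".npz")
        np.savez(tmp, params=maps.data, channel_names=np.array(PARAM_NAMES),
                 units=np.array(PARAM_UNITS))
        os.replace(tmp, path)
        return
    import h5py
    tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as f:
        d = f.create_dataset("params", data=maps.data)
        d.attrs["channel_names"] = list(PARAM_NAMES)
        d.attrs["units"] = list(PARAM_UNITS)
        if maps.objective is not None:
            f.create_dataset("objective", data=maps.objective)
        if maps.converged is not None:
            f.create_dataset("converged", data=maps.converged)
        if seed is not None:
            f.attrs["seed"] = seed
    os.replace(tmp, path)


def read_params(path: str) -> ParameterMaps:
    if str(path).endswith(".npz"):
        with np.load(path) as z:
            return ParameterMaps(z["params"])
    import h5py
    with h5py.File(path, "r") as f:
        if "params" not in f:
            raise InvalidInputError(f"{path}: expected a dataset 'params'")
        obj = f["objective"][...] if "objective" in f else None
        conv = f["converged"][...] if "converged" in f else None
        return ParameterMaps(f["params"][...], objective=obj, converged=conv)


def write_pair(path: str, truth: ParameterMaps, clean: MTFStack,
               noisy: MTFStack | None = None, seed=None):
    """Write a simulated (truth, clean MTF[, noisy MTF]) phantom pair."""
    import h5py
    tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as f:
        t = f.create_dataset("truth", data=truth.data)
        t.attrs["channel_names"] = list(PARAM_NAMES)
        t.attrs["units"] = list(PARAM_UNITS)
        m = f.create_dataset("mtf", data=clean.data)
        m.attrs["channel_names"] = list(clean.channel_names)
        if noisy is not None:
            f.create_dataset("mtf_noisy", data=noisy.data)
        if seed is not None:
            f.attrs["seed"] = seed
    os.replace(tmp, path)


def read_pair(path: str):
    import h5py
    with h5py.File(path, "r") as f:
        truth = ParameterMaps(f["truth"][...])
        clean = MTFStack(f["mtf"][...])
        noisy = MTFStack(f["mtf_noisy"][...]) if "mtf_noisy" in f else None
    return truth, clean, noisy


def write_series(path: str, frames, seed=None):
    """Write a temporal sequence of parameter maps: datasets ``times`` (T,)
    and ``params`` (T, n, n, 7)."""
    import h5py
    times = np.array([t for t, *_ in frames])
    data = np.stack([(m.data if isinstance(m, ParameterMaps) else np.asarray(m))
                     for _, m, *_ in frames])
    tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as f:
        f.create_dataset("times", data=times)
        d = f.create_dataset("params", data=data)
        d.attrs["channel_names"] = list(PARAM_NAMES)
        if seed is not None:
            f.attrs["seed"] = seed
    os.replace(tmp, path)


def read_series(path: str):
    import h5py
    with h5py.File(path, "r") as f:
        times = f["times"][...]
        data = f["params"][...]
    return [(float(t), ParameterMaps(d)) for t, d in zip(times, data)]


# ---------------------------------------------------------------------------
# raw fringe stacks
# ---------------------------------------------------------------------------

def write_phase_stack(path: str, triplets, geom: AcquisitionGeometry):
    """Write raw fringe images ordered (wavelength, phase, y, x) as a
    multi-page TIFF or an NPZ."""
    arr = np.stack([np.stack(t.images) for t in triplets])  # (3, 3, ny, nx)
    if str(path).endswith(".npz"):
        tmp = _atomic_path(path, suffix=".npz")
        np.savez(tmp, stack=arr, wavelengths=np.asarray(geom.wavelengths),
                 phases=np.asarray(geom.phases))
        os.replace(tmp, path)
        return
    import tifffile
    tmp = _atomic_path(path)
    tifffile.imwrite(tmp, arr.reshape(-1, *arr.shape[2:]).astype(np.float32))
    os.replace(tmp, path)


def read_stack(path: str, geom: AcquisitionGeometry | None = None):
    """Read a raw fringe container into a list of PhaseTriplet (one per
    wavelength), or an MTF container into an MTFStack.

    Recognized layouts: multi-page TIFF with 9 pages ordered (wavelength,
    phase); NPZ with a ``stack`` array of shape (3, 3, ny, nx) or an ``mtf``
    array; HDF5 with an ``mtf`` dataset.
    """
    geom = geom or AcquisitionGeometry()
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        import tifffile
        arr = tifffile.imread(p)
        if arr.ndim != 3 or arr.shape[0] != 9:
            raise InvalidInputError(
                f"{p}: expected 9 pages ordered (wavelength, phase), got "
                f"shape {arr.shape}")
        arr = arr.reshape(3, 3, *arr.shape[1:])
    elif p.endswith(".npz"):
        with np.load(p) as z:
            if "mtf" in z:
                return read_mtf(p)
            if "stack" not in z:
                raise InvalidInputError(
                    f"{p}: expected array 'stack' (wavelength, phase, y, x) "
                    "or 'mtf'")
            arr = z["stack"]
    elif p.endswith((".h5", ".hdf5")):
        return read_mtf(p)
    else:
        raise InvalidInputError(f"unrecognized container: {p}")
    return [PhaseTriplet(*arr[i], wavelength=geom.wavelengths[i],
                         phases=tuple(geom.phases))
            for i in range(3)]
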