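"""Container I/O, format converters and grid resampling.

The native container is HDF5 with layout

    /axis        attrs: n_points, bandwidth_hz, carrier_ppm, field_mhz
    /data        dataset "values" (complex), attr "domain" (time|freq)
    /masks/brain, /masks/scalp      boolean maps (volumes only)
    /provenance  attrs: seed, config (canonical JSON), config_hash,
                 package version

Datasets (training sets) store their arrays under /data and the lipid
bases of every synthetic subject under /subspaces/<id>.  NIfTI-MRS
export follows the convention of complex time-domain data along the
4th/spectral dimension with the dwell time in pixdim and a JSON header
extension carrying the spectrometer frequency, nucleus and chemical
shift reference.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import h5py
import numpy as np

from . import __version__
from .axis import SpectralAxis
from .lipid_l2 import LipidSubspace
from .nuisance import TrainingDataset
from .spectrum import MRSIVolume

__all__ = [
    "config_hash",
    "write_container",
    "read_container",
    "export_nifti_mrs",
    "import_nifti_mrs",
    "export_mask_nifti",
    "resample_to_grid",
    "ContainerError",
]

#: JSON header extension code used for MRS metadata.
_NIFTI_MRS_ECODE = 44


class ContainerError(ValueError):
    pass


def config_hash(config: dict[str, Any]) -> str:
    """SHA-256 over the canonical JSON serialization of a config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _write_axis(group: h5py.Group, axis: SpectralAxis) -> None:
    g = group.create_group("axis")
    g.attrs["n_points"] = axis.n_points
    g.attrs["bandwidth_hz"] = axis.bandwidth_hz
    g.attrs["carrier_ppm"] = axis.carrier_ppm
    g.attrs["field_mhz"] = axis.field_mhz


def _read_axis(group: h5py.Group) -> SpectralAxis:
    if "axis" not in group:
        raise ContainerError("malformed container: missing /axis group")
    a = group["axis"].attrs
    return SpectralAxis(
        n_points=int(a["n_points"]),
        bandwidth_hz=float(a["bandwidth_hz"]),
        carrier_ppm=float(a["carrier_ppm"]),
        field_mhz=float(a["field_mhz"]),
    )


def _write_provenance(f: h5py.File, seed: int | None, config: dict | None) -> None:
    g = f.create_group("provenance")
    config = config if config is not None else {}
    g.attrs["seed"] = -1 if seed is None else int(seed)
    g.attrs["config"] = json.dumps(config, sort_keys=True, default=str)
    g.attrs["config_hash"] = config_hash(config)
    g.attrs["version"] = __version__


def write_container(
    obj: MRSIVolume | TrainingDataset,
    path,
    seed: int | None = None,
    config: dict | None = None,
) -> str:
    """Write a volume or training dataset to the HDF5 container."""
    with h5py.File(path, "w") as f:
        _write_axis(f, obj.axis)
        _write_provenance(f, seed, config)
        if isinstance(obj, MRSIVolume):
            f.attrs["kind"] = "volume"
            d = f.create_group("data")
            d.create_dataset("values", data=obj.data)
            d.attrs["domain"] = obj.domain
            masks = f.create_group("masks")
            masks.create_dataset("brain", data=obj.brain_mask)
            masks.create_dataset("scalp", data=obj.scalp_mask)
        elif isinstance(obj, TrainingDataset):
            f.attrs["kind"] = "dataset"
            d = f.create_group("data")
            d.attrs["domain"] = "freq"
            for name in ("m", "lipid", "water", "x1", "x2"):
                d.create_dataset(name, data=getattr(obj, name))
            d.create_dataset("subject_ids", data=obj.subject_ids)
            d.attrs["ref_scale"] = obj.ref_scale
            subs = f.create_group("subspaces")
            for sid, sub in obj.subspaces.items():
                g = subs.create_group(str(sid))
                g.create_dataset("L", data=sub.L)
                g.attrs["beta"] = sub.beta
        else:
            raise TypeError(f"cannot store object of type {type(obj).__name__}")
    return str(path)


def read_container(path) -> MRSIVolume | TrainingDataset:
    """Read a container written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        axis = _read_axis(f)
        kind = f.attrs.get("kind")
        if "data" not in f:
            raise ContainerError("malformed container: missing /data group")
        d = f["data"]
        if kind == "volume":
            if "masks" not in f:
                raise ContainerError("malformed container: missing /masks group")
            return MRSIVolume(
                d["values"][()],
                axis,
                str(d.attrs["domain"]),
                brain_mask=f["masks/brain"][()],
                scalp_mask=f["masks/scalp"][()],
            )
        if kind == "dataset":
            subspaces = {
                int(sid): LipidSubspace(
                    g["L"][()], float(g.attrs["beta"]), axis
                )
                for sid, g in f["subspaces"].items()
            }
            return TrainingDataset(
                axis=axis,
                m=d["m"][()],
                lipid=d["lipid"][()],
                water=d["water"][()],
                x1=d["x1"][()],
                x2=d["x2"][()],
                subject_ids=d["subject_ids"][()],
                subspaces=subspaces,
                ref_scale=float(d.attrs["ref_scale"]),
            )
        raise ContainerError(f"unknown container kind: {kind!r}")


# ----------------------------------------------------------------------
# NIfTI-MRS
# ----------------------------------------------------------------------

def export_nifti_mrs(volume: MRSIVolume, path) -> str:
    """Write a volume as NIfTI-MRS (complex FID along the 4th dim)."""
    import nibabel as nib

    fid = volume.to_time().data  # (ny, nx, n_t)
    arr = np.transpose(fid, (1, 0, 2))[:, :, None, :].astype(np.complex64)
    img = nib.Nifti2Image(arr, affine=np.eye(4))
    img.header["pixdim"][4] = volume.axis.dwell_time
    meta = {
        "SpectrometerFrequency": [volume.axis.field_mhz],
        "ResonantNucleus": ["1H"],
        "ChemicalShiftReference": volume.axis.carrier_ppm,
    }
    ext = nib.nifti1.Nifti1Extension("comment", json.dumps(meta).encode())
    ext._code = _NIFTI_MRS_ECODE
    img.header.extensions.append(ext)
    nib.save(img, str(path))
    return str(path)


def import_nifti_mrs(path) -> MRSIVolume:
    import nibabel as nib

    img = nib.load(str(path))
    meta = None
    for ext in img.header.extensions:
        try:
            meta = json.loads(bytes(ext.get_content()).decode())
            if "SpectrometerFrequency" in meta:
                break
            meta = None
        except (ValueError, UnicodeDecodeError):
            continue
    if meta is None:
        raise ContainerError("not a NIfTI-MRS file: missing MRS header extension")
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ContainerError(f"expected 4-D NIfTI-MRS data, got {arr.ndim}-D")
    dwell = float(img.header["pixdim"][4])
    if dwell <= 0:
        raise ContainerError("missing or invalid dwell time in pixdim[4]")
    axis = SpectralAxis(
        n_points=arr.shape[3],
        bandwidth_hz=1.0 / dwell,
        carrier_ppm=float(meta.get("ChemicalShiftReference", 4.65)),
        field_mhz=float(meta["SpectrometerFrequency"][0]),
    )
    data = np.transpose(arr[:, :, 0, :], (1, 0, 2)).astype(complex)
    return MRSIVolume(data, axis, "time")


def export_mask_nifti(mask: np.ndarray, path) -> str:
    import nibabel as nib

    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8).T[:, :, None], affine=np.eye(4)
    )
    nib.save(img, str(path))
    return str(path)


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------

def resample_to_grid(x, target_axis: SpectralAxis, warn=None):
    """Interpolate a spectrum onto another ppm grid.

    Cubic-spline interpolation of real and imaginary parts over the ppm
    overlap; points outside the source coverage are zero.  Emits a
    warning (or calls ``warn``) when the overlap does not cover the
    0-9 ppm band.
    """
    import warnings

    from scipy.interpolate import CubicSpline

    from .spectrum import Spectrum

    spec = x.to_freq()
    src = x.axis
    s_lo, s_hi = src.ppm_range()
    t_lo, t_hi = target_axis.ppm_range()
    if min(s_hi, t_hi) <= max(s_lo, t_lo):
        raise ValueError("no ppm overlap between source and target axes")
    if max(s_lo, t_lo) > 0.0 or min(s_hi, t_hi) < 9.0:
        msg = (
            f"ppm overlap ({max(s_lo, t_lo):.2f}, {min(s_hi, t_hi):.2f}) does not "
            f"cover the 0-9 ppm band"
        )
        (warn or warnings.warn)(msg)
    # ascending ppm for the spline
    p_src = src.ppm[::-1]
    v_src = spec.data[::-1]
    cs_r = CubicSpline(p_src, v_src.real)
    cs_i = CubicSpline(p_src, v_src.imag)
    p_tgt = target_axis.ppm
    inside = (p_tgt >= s_lo) & (p_tgt <= s_hi)
    out = np.zeros(target_axis.n_points, dtype=complex)
    out[inside] = cs_r(p_tgt[inside]) + 1j * cs_i(p_tgt[inside])
    return Spectrum(out, target_axis, "freq")
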