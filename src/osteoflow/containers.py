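"""HDF5 containers for channel data, IQ sequences and flow fields.

There is no community standard for research ultrasound channel data; one
HDF5 layout is used throughout:

* ``data.h5``  -- /rf (frames x transmits x elements x samples, float32)
  with acquisition metadata as attributes, /truth/* ground-truth arrays.
* ``iq.h5``    -- /iq (nx x nz x frames, complex64) with grid attributes.
* ``flow.h5``  -- /pd, /v_axial, /v_radial, /drift plus the ROI series.

Write-then-read round-trips are bit-identical for array datasets.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np

from osteoflow.acoustics import ImagingGrid, LayeredMediumModel, ProbeModel
from osteoflow.reconstruction import IQImageSequence
from osteoflow.simulator import AcquisitionProtocol, ChannelDataCube


class MissingDatasetError(KeyError):
    pass


def array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _require(h5: h5py.File, name: str) -> h5py.Dataset:
    if name not in h5:
        raise MissingDatasetError(f"dataset {name!r} missing from {h5.filename}")
    return h5[name]


def write_channel_data(path: str | Path, cube: ChannelDataCube,
                       truth: dict[str, np.ndarray] | None = None) -> None:
    with h5py.File(path, "w") as h5:
        d = h5.create_dataset("rf", data=cube.rf.astype(np.float32))
        d.attrs["sample_rate_mhz"] = cube.sample_rate
        d.attrs["t0_us"] = cube.t0
        p = cube.protocol
        d.attrs["mode"] = p.mode
        d.attrs["angles_deg"] = np.asarray(p.angles_deg)
        d.attrs["frames"] = p.frames
        d.attrs["frame_rate_hz"] = p.frame_rate
        d.attrs["ensemble_size"] = p.ensemble_size
        d.attrs["prf_hz"] = p.prf
        d.attrs["intra_frame_motion"] = p.intra_frame_motion
        pr = cube.probe
        d.attrs["element_count"] = pr.element_count
        d.attrs["pitch_mm"] = pr.pitch
        d.attrs["center_frequency_mhz"] = pr.center_frequency
        d.attrs["sampling_frequency_mhz"] = pr.sampling_frequency
        d.attrs["pulse_bandwidth"] = pr.pulse_bandwidth
        me = cube.medium
        d.attrs["interface_skin_bone_mm"] = me.interface_skin_bone_depth
        d.attrs["interface_bone_marrow_mm"] = me.interface_bone_marrow_depth
        d.attrs["c_tissue_m_s"] = me.c_tissue
        d.attrs["c_marrow_m_s"] = me.c_marrow
        d.attrs["bone_speed_params"] = np.asarray(me.bone_speed_params)
        if truth:
            g = h5.create_group("truth")
            for k, v in truth.items():
                g.create_dataset(k, data=v)


def read_channel_data(path: str | Path) -> ChannelDataCube:
    with h5py.File(path, "r") as h5:
        d = _require(h5, "rf")
        a = d.attrs
        protocol = AcquisitionProtocol(
            mode=str(a["mode"]),
            angles_deg=tuple(np.asarray(a["angles_deg"]).tolist()),
            frames=int(a["frames"]), frame_rate=float(a["frame_rate_hz"]),
            ensemble_size=int(a["ensemble_size"]), prf=float(a["prf_hz"]),
            intra_frame_motion=bool(a["intra_frame_motion"]))
        probe = ProbeModel(int(a["element_count"]), float(a["pitch_mm"]),
                           float(a["center_frequency_mhz"]),
                           float(a["sampling_frequency_mhz"]),
                           float(a["pulse_bandwidth"]))
        medium = LayeredMediumModel(
            float(a["interface_skin_bone_mm"]),
            float(a["interface_bone_marrow_mm"]),
            float(a["c_tissue_m_s"]), float(a["c_marrow_m_s"]),
            tuple(np.asarray(a["bone_speed_params"]).tolist()))
        return ChannelDataCube(rf=d[...], sample_rate=float(a["sample_rate_mhz"]),
                               t0=float(a["t0_us"]), protocol=protocol,
                               probe=probe, medium=medium)


def read_truth(path: str | Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as h5:
        if "truth" not in h5:
            return {}
        return {k: h5["truth"][k][...] for k in h5["truth"]}


def write_iq(path: str | Path, seq: IQImageSequence) -> None:
    with h5py.File(path, "w") as h5:
        d = h5.create_dataset("iq", data=seq.iq.astype(np.complex64))
        d.attrs["x_coords_mm"] = seq.grid.x_coords
        d.attrs["z_coords_mm"] = seq.grid.z_coords
        d.attrs["frame_rate_hz"] = seq.frame_rate
        d.attrs["carrier_frequency_mhz"] = seq.carrier_frequency
        if seq.medium is not None:
            m = seq.medium
            d.attrs["interface_skin_bone_mm"] = m.interface_skin_bone_depth
            d.attrs["interface_bone_marrow_mm"] = m.interface_bone_marrow_depth
            d.attrs["c_tissue_m_s"] = m.c_tissue
            d.attrs["c_marrow_m_s"] = m.c_marrow
            d.attrs["bone_speed_params"] = np.asarray(m.bone_speed_params)


def read_iq(path: str | Path) -> IQImageSequence:
    with h5py.File(path, "r") as h5:
        d = _require(h5, "iq")
        a = d.attrs
        grid = ImagingGrid(np.asarray(a["x_coords_mm"]),
                           np.asarray(a["z_coords_mm"]))
        medium = None
        if "c_tissue_m_s" in a:
            medium = LayeredMediumModel(
                float(a["interface_skin_bone_mm"]),
                float(a["interface_bone_marrow_mm"]),
                float(a["c_tissue_m_s"]), float(a["c_marrow_m_s"]),
                tuple(np.asarray(a["bone_speed_params"]).tolist()))
        return IQImageSequence(iq=d[...], grid=grid,
                               frame_rate=float(a["frame_rate_hz"]),
                               carrier_frequency=float(a["carrier_frequency_mhz"]),
                               medium=medium)


def write_flow(path: str | Path, datasets: dict[str, np.ndarray],
               attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as h5:
        for name, arr in datasets.items():
            h5.create_dataset(name, data=arr)
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def read_flow(path: str | Path, names: list[str] | None = None
              ) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as h5:
        keys = names if names is not None else list(h5.keys())
        out = {}
        for k in keys:
            out[k] = _require(h5, k)[...]
        return out
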