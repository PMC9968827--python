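"""File formats: meshes, montages, recordings, CSD profiles, topographies.

All writers embed explicit unit fields and provenance attributes (package
version, RNG seed, configuration hash) because the processing chain crosses
several unit systems (mV, uA/mm^3, nA*m, uV, mm, ms) and silent unit
mismatches are the dominant failure mode.  Array checksums (sha256 of the
raw bytes) support bit-identical reproducibility checks independent of
container-format metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .csd import CSDProfile
from .dipole import DipoleSource
from .extracellular import LaminarRecording
from .headmodel import ElectrodeMontage, ScalpTopography
from .synthetic import CompartmentCurrentSet

__all__ = [
    "array_checksum",
    "read_mesh",
    "write_mesh",
    "canonical_mesh",
    "read_montage_tsv",
    "write_montage_tsv",
    "write_recording_h5",
    "read_recording_h5",
    "write_recording_csv",
    "read_recording_csv",
    "write_csd_h5",
    "read_csd_h5",
    "write_currents_h5",
    "read_currents_h5",
    "write_topography_csv",
    "read_topography_csv",
    "write_dipole",
    "read_dipole",
]

_VERSION = "0.1.0"


def array_checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _provenance(extra: dict | None = None) -> dict:
    meta = {"package_version": _VERSION}
    if extra:
        meta.update(extra)
    return meta


# -- meshes ------------------------------------------------------------------


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(str(path), process=True)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangle mesh")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    path = Path(path)
    kind = path.suffix.lower().lstrip(".")
    if kind not in {"stl", "off", "ply"}:
        raise ValueError(f"unsupported mesh format {kind!r}")
    if kind == "stl":
        data = trimesh.exchange.stl.export_stl_ascii(mesh)
    elif kind == "ply":
        data = mesh.export(file_type="ply", encoding="ascii")
    else:
        data = mesh.export(file_type="off")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def canonical_mesh(mesh: trimesh.Trimesh, decimals: int = 6):
    """Canonical (vertices, faces) arrays for cross-format comparison.

    Vertices are rounded and lexicographically sorted; each face is rotated so
    its smallest vertex index comes first (orientation preserved) and faces
    are sorted.
    """
    verts = np.round(np.asarray(mesh.vertices, float), decimals)
    order = np.lexsort(verts.T[::-1])
    verts = verts[order]
    remap = np.empty(len(order), int)
    remap[order] = np.arange(len(order))
    faces = remap[np.asarray(mesh.faces, int)]
    roll = np.argmin(faces, axis=1)
    faces = np.array([np.roll(f, -r) for f, r in zip(faces, roll)])
    faces = faces[np.lexsort(faces.T[::-1])]
    return verts, faces


# -- montages ----------------------------------------------------------------


def write_montage_tsv(montage: ElectrodeMontage, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "label": montage.labels,
            "x_mm": montage.positions_mm[:, 0],
            "y_mm": montage.positions_mm[:, 1],
            "z_mm": montage.positions_mm[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_montage_tsv(path: str | Path) -> ElectrodeMontage:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage TSV must have columns {sorted(required)}")
    labels = [str(x) for x in df["label"]]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels in montage")
    return ElectrodeMontage(labels, df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


# -- laminar recordings ------------------------------------------------------


def write_recording_h5(rec: LaminarRecording, path: str | Path,
                       meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("depths_mm", data=rec.depths_mm, track_times=False)
        f.create_dataset("lfp_mv", data=rec.lfp_mv, track_times=False)
        f.attrs["dt_ms"] = rec.dt_ms
        f.attrs["sigma_s_m"] = rec.sigma_s_m
        f.attrs["units"] = "depths: mm; lfp: mV; dt: ms; sigma: S/m"
        f.attrs["events_ms"] = json.dumps(rec.events_ms)
        f.attrs["provenance"] = json.dumps(_provenance(meta))


def read_recording_h5(path: str | Path) -> LaminarRecording:
    with h5py.File(path, "r") as f:
        return LaminarRecording(
            depths_mm=f["depths_mm"][...],
            lfp_mv=f["lfp_mv"][...],
            dt_ms=float(f.attrs["dt_ms"]),
            sigma_s_m=float(f.attrs["sigma_s_m"]),
            events_ms=json.loads(f.attrs.get("events_ms", "{}")),
        )


def write_recording_csv(rec: LaminarRecording, path: str | Path) -> None:
    """First column depth (mm); remaining columns samples; header = times (ms)."""
    cols = ["depth_mm"] + [f"{t:.6f}" for t in rec.time_ms]
    df = pd.DataFrame(
        np.column_stack([rec.depths_mm, rec.lfp_mv]), columns=cols
    )
    with open(path, "w") as fh:
        fh.write(f"# laminar LFP; units mV; dt_ms={rec.dt_ms}; sigma_s_m={rec.sigma_s_m}\n")
        df.to_csv(fh, index=False)


def read_recording_csv(path: str | Path) -> LaminarRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing unit header line")
        fields = {
            k.strip(): v.strip()
            for k, v in (kv.split("=") for kv in header.split(";") if "=" in kv)
        }
        df = pd.read_csv(fh)
    return LaminarRecording(
        depths_mm=df["depth_mm"].to_numpy(float),
        lfp_mv=df.iloc[:, 1:].to_numpy(float),
        dt_ms=float(fields["dt_ms"]),
        sigma_s_m=float(fields["sigma_s_m"].strip()),
    )


# -- CSD profiles ------------------------------------------------------------


def write_csd_h5(profile: CSDProfile, path: str | Path, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z_mm", data=profile.z_mm, track_times=False)
        f.create_dataset("csd_ua_mm3", data=profile.csd_ua_mm3, track_times=False)
        f.attrs["dt_ms"] = profile.dt_ms
        f.attrs["t0_ms"] = profile.t0_ms
        f.attrs["method"] = profile.method
        f.attrs["params"] = json.dumps(profile.params, default=float)
        f.attrs["units"] = "z: mm (positive toward pia); csd: uA/mm^3; t: ms"
        f.attrs["provenance"] = json.dumps(_provenance(meta))


def read_csd_h5(path: str | Path) -> CSDProfile:
    with h5py.File(path, "r") as f:
        return CSDProfile(
            z_mm=f["z_mm"][...],
            csd_ua_mm3=f["csd_ua_mm3"][...],
            dt_ms=float(f.attrs["dt_ms"]),
            method=str(f.attrs["method"]),
            params=json.loads(f.attrs.get("params", "{}")),
            t0_ms=float(f.attrs.get("t0_ms", 0.0)),
        )


# -- compartment currents ----------------------------------------------------


def write_currents_h5(currents: CompartmentCurrentSet, path: str | Path,
                      meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords_mm", data=currents.coords_mm, track_times=False)
        f.create_dataset("currents_na", data=currents.currents_na, track_times=False)
        f.create_dataset("neuron_index", data=currents.neuron_index, track_times=False)
        f.create_dataset(
            "labels",
            data=np.array(currents.labels, dtype=h5py.string_dtype()),
            track_times=False,
        )
        f.attrs["dt_ms"] = currents.dt_ms
        f.attrs["units"] = "coords: mm; currents: nA; dt: ms"
        f.attrs["provenance"] = json.dumps(_provenance(meta))


def read_currents_h5(path: str | Path) -> CompartmentCurrentSet:
    with h5py.File(path, "r") as f:
        return CompartmentCurrentSet(
            coords_mm=f["coords_mm"][...],
            currents_na=f["currents_na"][...],
            dt_ms=float(f.attrs["dt_ms"]),
            neuron_index=f["neuron_index"][...],
            labels=[s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][...]],
        )


# -- topographies ------------------------------------------------------------


def write_topography_csv(topo: ScalpTopography, path: str | Path) -> None:
    if topo.values_uv.ndim != 1:
        raise ValueError("CSV topographies must be static maps")
    df = pd.DataFrame({"label": topo.labels, "value_uv": topo.values_uv})
    with open(path, "w") as fh:
        fh.write(f"# scalp topography; units uV; condition={topo.condition}\n")
        df.to_csv(fh, index=False)


def read_topography_csv(path: str | Path) -> ScalpTopography:
    with open(path) as fh:
        header = fh.readline()
        condition = ""
        if header.startswith("#"):
            for kv in header.split(";"):
                if "condition=" in kv:
                    condition = kv.split("=", 1)[1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return ScalpTopography(
        [str(x) for x in df["label"]], df["value_uv"].to_numpy(float), condition
    )


# -- dipoles -----------------------------------------------------------------


def write_dipole(dip: DipoleSource, json_path: str | Path,
                 trace_path: str | Path | None = None) -> None:
    header = {
        "position_mm": dip.position_mm.tolist(),
        "orientation": dip.orientation.tolist(),
        "r_c_mm": dip.r_c_mm,
        "dt_ms": dip.dt_ms,
        "provenance_tag": dip.provenance,
        "units": "position: mm; amplitude: nA*m; dt: ms",
        "meta": _provenance(),
    }
    if trace_path is not None:
        header["trace_file"] = str(Path(trace_path).name)
        pd.DataFrame(
            {"time_ms": np.arange(len(dip.amplitude_nam)) * dip.dt_ms,
             "amplitude_nam": dip.amplitude_nam}
        ).to_csv(trace_path, index=False)
    else:
        header["amplitude_nam"] = dip.amplitude_nam.tolist()
    Path(json_path).write_text(json.dumps(header, indent=1))


def read_dipole(json_path: str | Path) -> DipoleSource:
    header = json.loads(Path(json_path).read_text())
    if "trace_file" in header:
        trace = pd.read_csv(Path(json_path).parent / header["trace_file"])
        amplitude = trace["amplitude_nam"].to_numpy(float)
    else:
        amplitude = np.asarray(header["amplitude_nam"], float)
    return DipoleSource(
        position_mm=np.asarray(header["position_mm"], float),
        orientation=np.asarray(header["orientation"], float),
        amplitude_nam=amplitude,
        dt_ms=float(header["dt_ms"]),
        r_c_mm=float(header["r_c_mm"]),
        provenance=header.get("provenance_tag", "CSD"),
    )
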