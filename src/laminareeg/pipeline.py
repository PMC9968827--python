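"""End-to-end pipeline: simulate -> LFP -> CSD -> dipole -> EEG -> metrics.

``forward_three_ways`` is the workhorse: for a simulated column placed at a
cortical site it computes scalp EEG three ways -

* ground truth: every compartment's transmembrane current as a monopole
  source through the BEM (the compartment-based solution);
* STC single-dipole: the summed-transmembrane-currents dipole through the
  BEM dipolar solution;
* CSD single-dipole: virtual laminar electrodes record the column LFP, the
  spline-iCSD profile is integrated into a dipole amplitude with fixed
  (column-normal) orientation, and that dipole is forward-modeled.

``run_pipeline`` wires the full chain from a YAML-able configuration and
persists every stage with array checksums so reruns can be verified to be
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import io as leio
from .csd import spline_icsd, standard_csd
from .dipole import DipoleSource, dipole_from_csd, dipole_from_stc
from .extracellular import laminar_electrode_positions, lfp_point_source, lowpass
from .headmodel import BemSolver, HeadModel, build_nested_spheres, place_montage
from .metrics import column_depth, mag, rdm
from .synthetic import (
    CompartmentCurrentSet,
    PopulationSpec,
    StimulusSpec,
    place_population,
    simulate_population,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "column_basis",
    "forward_three_ways",
    "simulate_column_currents",
    "candidate_source_geometry",
]


def candidate_source_geometry(brain_radius_mm: float = 30.0,
                              depth_mm: float = 3.0) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Fixed geometry of the five candidate cortical sources.

    Idealized left-hemisphere visual-attention network sources on the sphere
    head model (y anterior, z superior, x right): two occipital sources (one
    gyral/radial, one sulcal/tangential), two parietal sources, and one
    frontal source.  Returns ``{label: (position_mm, unit_orientation)}``.
    """
    def unit(v):
        v = np.asarray(v, float)
        return v / np.linalg.norm(v)

    specs = {
        "V4": ([-0.55, -0.75, 0.37], None),  # posterolateral gyrus, radial
        "lusV4": ([-0.40, -0.85, 0.35], [0.0, 0.4, 1.0]),  # sulcal, tangential
        "LIP": ([-0.45, -0.35, 0.82], [-0.8, 0.6, 0.0]),  # sulcal bank
        "7a": ([-0.55, -0.25, 0.79], None),  # parietal gyrus, radial
        "FEF": ([-0.45, 0.60, 0.66], [0.7, 0.0, 0.7]),  # frontal sulcus
    }
    out = {}
    for lab, (direction, orient) in specs.items():
        d = unit(direction)
        pos = d * (brain_radius_mm - depth_mm)
        if orient is None:
            o = d
        else:
            o = np.asarray(orient, float)
            o = unit(o - (o @ d) * d)  # tangential component
        out[lab] = (pos, o)
    return out


def column_basis(normal: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows t1, t2, n) for a column with outward normal n.

    Column-frame vectors map to the head frame as ``v_head = v_col @ basis``.
    """
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(helper, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.vstack([t1, t2, n])


def simulate_column_currents(
    population: PopulationSpec,
    stimulus: StimulusSpec,
    seed: int,
    *,
    duration_ms: float = 120.0,
    dt_ms: float = 0.1,
    events: bool = True,
) -> CompartmentCurrentSet:
    """Place and simulate one column with a seeded generator."""
    rng = np.random.default_rng(seed)
    neurons = place_population(population, rng)
    return simulate_population(
        neurons, stimulus, rng, duration_ms=duration_ms, dt_ms=dt_ms, events=events
    )


def forward_three_ways(
    solver: BemSolver,
    electrode_positions_mm: np.ndarray,
    currents: CompartmentCurrentSet,
    site_position_mm: np.ndarray,
    site_normal: np.ndarray,
    *,
    r_c_mm: float = 1.5,
    csd_method: str = "spline",
    csd_diameter_mm: float = 3.0,
    sigma_tissue: float = 0.33,
    n_laminar: int = 17,
    laminar_spacing_mm: float = 0.1,
    time_stride: int = 10,
    lowpass_hz: float = 100.0,
    pia_depth_mm: float = 2.0,
) -> dict:
    """Ground-truth / STC-dipole / CSD-dipole EEG for one column placement.

    ``site_position_mm`` lies on the innermost head-model surface; the column
    pia is placed ``pia_depth_mm`` below it along the inward normal (the BEM
    brain surface is a smoothed envelope, so cortical tissue sits beneath it;
    this also keeps every source strictly inside the surface).

    Returns a dict with the three (n_electrodes, n_t) EEG arrays (volts,
    average reference), the two dipole amplitude traces, the laminar
    recording and CSD profile, and the time indices kept after striding.
    """
    basis = column_basis(site_normal)
    site = np.asarray(site_position_mm, float) - pia_depth_mm * basis[2]
    keep = np.arange(0, currents.n_timepoints, time_stride)

    # --- ground truth: compartment monopoles through the BEM
    coords_head = site + currents.coords_mm @ basis
    eeg_gt = solver.forward_monopoles(
        coords_head, currents.currents_na[:, keep], electrode_positions_mm
    )

    # --- STC single dipole at the geometric center of the column
    moment_col = dipole_from_stc(currents)  # (3, n_t) nA*m, column frame
    z_center = 0.5 * (currents.coords_mm[:, 2].min() + currents.coords_mm[:, 2].max())
    r_m_col = np.array([0.0, 0.0, z_center])
    r_m_head = site + r_m_col @ basis
    moment_head = basis.T @ moment_col[:, keep]
    from .headmodel import v0_dipole

    v0 = v0_dipole((r_m_head, moment_head), solver.model.sigma_brain, solver.vertices_mm)
    eeg_stc = solver.electrode_potentials(electrode_positions_mm, v0)

    # --- CSD single dipole from virtual laminar electrodes
    elec_pos_col, depths = laminar_electrode_positions(
        n=n_laminar, spacing_mm=laminar_spacing_mm
    )
    rec = lfp_point_source(currents, elec_pos_col, sigma_tissue,
                           electrode_depths_mm=depths)
    rec = lowpass(rec, lowpass_hz)
    if csd_method == "spline":
        profile = spline_icsd(rec, diameter_mm=csd_diameter_mm, sigma_s_m=sigma_tissue)
    elif csd_method == "standard":
        profile = standard_csd(rec)
    else:
        raise ValueError(f"unknown CSD method {csd_method!r}")
    amp = dipole_from_csd(profile, r_c_mm=r_c_mm)  # nA*m along column normal
    z_m = 0.5 * (profile.z_mm[0] + profile.z_mm[-1])
    dip_pos = site + np.array([0.0, 0.0, z_m]) @ basis
    dip = DipoleSource(
        position_mm=dip_pos,
        orientation=basis[2],
        amplitude_nam=amp[keep],
        dt_ms=currents.dt_ms * time_stride,
        r_c_mm=r_c_mm,
        provenance="CSD",
    )
    eeg_csd = solver.forward_dipole(dip, electrode_positions_mm)

    stc_dip = DipoleSource(
        position_mm=r_m_head,
        orientation=basis[2],
        amplitude_nam=moment_col[2, keep],
        dt_ms=currents.dt_ms * time_stride,
        r_c_mm=r_c_mm,
        provenance="STC",
    )
    return {
        "eeg_ground_truth": eeg_gt,
        "eeg_stc": eeg_stc,
        "eeg_csd": eeg_csd,
        "csd_dipole": dip,
        "stc_dipole": stc_dip,
        "stc_moment_col": moment_col,
        "recording": rec,
        "csd_profile": profile,
        "kept_indices": keep,
        "dt_out_ms": currents.dt_ms * time_stride,
        "column_center_mm": r_m_head,
        "pia_position_mm": site,
    }


# ---------------------------------------------------------------------------
# configured end-to-end run
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of a full simulate-to-topography run."""

    seed: int = 0
    output_dir: str = "pipeline_out"
    n_l3: int = 220
    n_l5: int = 100
    stimulus_mean_na: float = 1.90
    stimulus_sd_na: float = 0.3
    duration_ms: float = 120.0
    dt_ms: float = 0.1
    n_laminar: int = 17
    laminar_spacing_mm: float = 0.1
    csd_method: str = "spline"
    csd_diameter_mm: float = 3.0
    sigma_tissue: float = 0.33
    r_c_mm: float = 1.5
    head_radii_mm: tuple[float, float, float] = (30.0, 35.0, 38.0)
    head_conductivities: tuple[float, float, float, float] = (0.33, 0.0063, 0.43, 0.0)
    subdivisions: int = 2
    mesh_paths: list[str] = dc_field(default_factory=list)
    montage_system: str = "10-10"
    site_vertex: int = 0
    time_stride: int = 10
    analysis_window_ms: tuple[float, float] = (20.0, 100.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in self.mesh_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"mesh file not found: {p}")
        if self.csd_method not in ("spline", "standard"):
            raise ValueError("csd_method must be 'spline' or 'standard'")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _head_model(cfg: PipelineConfig) -> HeadModel:
    if cfg.mesh_paths:
        surfaces = [leio.read_mesh(p) for p in cfg.mesh_paths]
        return HeadModel(surfaces, list(cfg.head_conductivities)[: len(surfaces) + 1])
    return build_nested_spheres(
        cfg.head_radii_mm, cfg.subdivisions, cfg.head_conductivities
    )


def run_pipeline(cfg: PipelineConfig, solver: BemSolver | None = None) -> dict:
    """Execute the full chain and persist per-stage artifacts + manifest.

    Returns a manifest dict (also written to ``manifest.json``) with the
    seed, configuration hash, per-stage output files and array checksums.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "checksums": {},
    }

    def fail(stage, err):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # stage 1: simulate
    try:
        currents = simulate_column_currents(
            PopulationSpec(n_l3=cfg.n_l3, n_l5=cfg.n_l5),
            StimulusSpec(mean_na=cfg.stimulus_mean_na, sd_na=cfg.stimulus_sd_na),
            cfg.seed,
            duration_ms=cfg.duration_ms,
            dt_ms=cfg.dt_ms,
        )
        leio.write_currents_h5(currents, out / "currents.h5",
                               meta={"seed": cfg.seed, "config_hash": cfg.config_hash()})
        manifest["stages"]["simulate"] = "currents.h5"
        manifest["checksums"]["currents"] = leio.array_checksum(currents.currents_na)
    except Exception as err:  # noqa: BLE001
        fail("simulate", err)

    # stage 2: head model + montage
    try:
        model = _head_model(cfg)
        bem = solver if solver is not None else BemSolver(model)
        montage = place_montage(bem.model.scalp, cfg.montage_system)
        leio.write_montage_tsv(montage, out / "montage.tsv")
        manifest["stages"]["montage"] = "montage.tsv"
    except Exception as err:  # noqa: BLE001
        fail("head_model", err)

    # stage 3-6: LFP, CSD, dipoles, forward EEG
    try:
        brain = bem.model.surfaces[0]
        site = np.asarray(brain.vertices[cfg.site_vertex % len(brain.vertices)], float)
        from .dipole import orient_from_mesh

        normal = orient_from_mesh(brain, site)
        res = forward_three_ways(
            bem, montage.positions_mm, currents, site, normal,
            r_c_mm=cfg.r_c_mm, csd_method=cfg.csd_method,
            csd_diameter_mm=cfg.csd_diameter_mm, sigma_tissue=cfg.sigma_tissue,
            n_laminar=cfg.n_laminar, laminar_spacing_mm=cfg.laminar_spacing_mm,
            time_stride=cfg.time_stride,
        )
        leio.write_recording_h5(res["recording"], out / "lfp.h5",
                                meta={"seed": cfg.seed})
        leio.write_csd_h5(res["csd_profile"], out / "csd.h5", meta={"seed": cfg.seed})
        leio.write_dipole(res["csd_dipole"], out / "dipole_csd.json",
                          out / "dipole_csd_trace.csv")
        leio.write_dipole(res["stc_dipole"], out / "dipole_stc.json",
                          out / "dipole_stc_trace.csv")
        manifest["stages"].update(
            lfp="lfp.h5", csd="csd.h5",
            dipole=["dipole_csd.json", "dipole_stc.json"],
        )
        manifest["checksums"].update(
            lfp=leio.array_checksum(res["recording"].lfp_mv),
            csd=leio.array_checksum(res["csd_profile"].csd_ua_mm3),
            dipole_csd=leio.array_checksum(res["csd_dipole"].amplitude_nam),
            dipole_stc=leio.array_checksum(res["stc_dipole"].amplitude_nam),
            eeg_ground_truth=leio.array_checksum(res["eeg_ground_truth"]),
        )
    except Exception as err:  # noqa: BLE001
        fail("forward", err)

    # stage 7: topography + agreement metrics
    try:
        from .headmodel import ScalpTopography

        dt_out = res["dt_out_ms"]
        t = np.arange(res["eeg_ground_truth"].shape[1]) * dt_out
        w0, w1 = cfg.analysis_window_ms
        mask = (t >= w0) & (t <= w1)
        topo = ScalpTopography(
            montage.labels,
            1e6 * res["eeg_ground_truth"][:, mask].mean(axis=1),
            condition="ground_truth",
        )
        leio.write_topography_csv(topo, out / "topography.csv")
        agreement = {
            "rdm_stc": float(rdm(res["eeg_ground_truth"].ravel(), res["eeg_stc"].ravel())),
            "rdm_csd": float(rdm(res["eeg_ground_truth"].ravel(), res["eeg_csd"].ravel())),
            "mag_stc": float(mag(res["eeg_ground_truth"].ravel(), res["eeg_stc"].ravel())),
            "mag_csd": float(mag(res["eeg_ground_truth"].ravel(), res["eeg_csd"].ravel())),
            "column_depth_mm": column_depth(bem.model.scalp, site),
        }
        (out / "agreement.json").write_text(json.dumps(agreement, indent=1))
        manifest["stages"]["topography"] = "topography.csv"
        manifest["stages"]["agreement"] = "agreement.json"
        manifest["checksums"]["topography"] = leio.array_checksum(topo.values_uv)
        manifest["agreement"] = agreement
    except Exception as err:  # noqa: BLE001
        fail("metrics", err)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
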