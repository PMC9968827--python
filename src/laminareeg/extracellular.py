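"""Extracellular potentials at a laminar electrode array.

The local field potential is the superposition of point-source contributions
from every compartment's transmembrane current in an infinite homogeneous
medium of conductivity sigma:

    V(r_e, t) = (1 / 4 pi sigma) * sum_c I_c(t) / max(|r_e - r_c|, r_min)

with the distance clamped at the compartment radius to guard the point-source
singularity.  Signals are low-pass filtered with a zero-phase 4th-order
Butterworth filter (100 Hz default), matching the bandwidth of field
potentials used for current source density analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .synthetic import CompartmentCurrentSet

__all__ = ["LaminarRecording", "laminar_electrode_positions", "lfp_point_source", "lowpass"]


@dataclass
class LaminarRecording:
    """Depth-ordered LFP time series from a linear electrode array.

    ``depths_mm`` increase with depth below the pia; the LFP matrix is in mV.
    """

    depths_mm: np.ndarray  # (n_elec,)
    lfp_mv: np.ndarray  # (n_elec, n_t)
    dt_ms: float
    sigma_s_m: float = 0.33
    events_ms: dict = field(default_factory=dict)
    layer_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, float)
        self.lfp_mv = np.asarray(self.lfp_mv, float)
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ValueError("electrode depths must be strictly increasing")
        if self.lfp_mv.shape[0] != len(self.depths_mm):
            raise ValueError("LFP rows must match electrode count")
        if self.sigma_s_m <= 0:
            raise ValueError("conductivity must be positive")

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.lfp_mv.shape[1]) * self.dt_ms


def laminar_electrode_positions(
    n: int = 17,
    spacing_mm: float = 0.1,
    start_depth_mm: float = 0.0,
    axis_origin_mm: np.ndarray | None = None,
    axis_direction: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (n, 3) and depths (n,) of a co-linear laminar array.

    By default the array runs down the column axis (x = y = 0) in the column
    frame, with the first contact at the pia.  ``axis_origin_mm`` /
    ``axis_direction`` place the array in an arbitrary frame (direction points
    from the pia into the depth).
    """
    depths = start_depth_mm + spacing_mm * np.arange(n)
    if axis_origin_mm is None:
        positions = np.column_stack([np.zeros(n), np.zeros(n), -depths])
    else:
        d = np.asarray(axis_direction, float)
        d = d / np.linalg.norm(d)
        positions = np.asarray(axis_origin_mm, float)[None, :] + depths[:, None] * d
    return positions, depths


def lfp_point_source(
    currents: CompartmentCurrentSet,
    electrode_positions_mm: np.ndarray,
    sigma_s_m: float = 0.33,
    *,
    electrode_depths_mm: np.ndarray | None = None,
    r_min_mm: np.ndarray | float | None = None,
    compartment_radii_mm: np.ndarray | None = None,
) -> LaminarRecording:
    """Point-source LFP of all compartments at the given electrodes (mV).

    ``r_min_mm`` defaults to each compartment's radius.  If the electrodes are
    not co-linear a warning is emitted but the potentials are still computed.
    """
    if sigma_s_m <= 0:
        raise ValueError("conductivity must be positive")
    pos = np.atleast_2d(np.asarray(electrode_positions_mm, float))
    if pos.shape[0] >= 3:
        rel = pos - pos[0]
        rel = rel[1:]
        cross = np.cross(rel[:1], rel)
        if np.max(np.linalg.norm(cross, axis=1)) > 1e-9 * np.max(
            np.linalg.norm(rel, axis=1)
        ):
            warnings.warn("electrodes are not co-linear; computing anyway")
    if r_min_mm is None:
        r_min = (
            currents.meta.get("radii_mm")
            if compartment_radii_mm is None
            else compartment_radii_mm
        )
        if r_min is None:
            r_min = 0.0
    else:
        r_min = r_min_mm
    r_min = np.broadcast_to(np.asarray(r_min, float), (currents.coords_mm.shape[0],))

    diff = pos[:, None, :] - currents.coords_mm[None, :, :]
    dist = np.linalg.norm(diff, axis=2)  # (n_elec, n_comp)
    dist = np.maximum(dist, r_min[None, :])
    if np.any(dist == 0):
        raise ValueError("electrode coincides with a compartment center and r_min = 0")
    # nA / (S/m * mm) -> 1e-3 mV
    weights = 1e-3 / (4 * math.pi * sigma_s_m * dist)
    lfp = weights @ currents.currents_na
    if electrode_depths_mm is None:
        electrode_depths_mm = -pos[:, 2]  # column frame: depth = -z
    return LaminarRecording(
        depths_mm=electrode_depths_mm,
        lfp_mv=lfp,
        dt_ms=currents.dt_ms,
        sigma_s_m=sigma_s_m,
    )


def lowpass(recording: LaminarRecording, cutoff_hz: float = 100.0, order: int = 4) -> LaminarRecording:
    """Zero-phase Butterworth low-pass; unit DC gain, unchanged shape."""
    fs = 1000.0 / recording.dt_ms
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    return replace(recording, lfp_mv=filtfilt(b, a, recording.lfp_mv, axis=1))
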