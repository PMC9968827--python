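"""Equivalent current dipoles from CSD profiles or compartment currents.

A cortical column is summarized by a point dipole at its center.  Two
estimators are provided:

* ``dipole_from_csd`` - the CSD single-dipole: the column is a cylinder of
  radius ``r_c`` and the dipole amplitude is the first depth moment of the
  volumetric CSD, ``d_z(t) = pi r_c^2 * integral CSD(z, t) (z - z_m) dz``,
  evaluated with the trapezoid rule on the profile's own grid.  Only the
  component along the column axis is available from laminar CSD; the dipole
  orientation is taken from the cortical-surface normal.

* ``dipole_from_stc`` - the summed-transmembrane-currents dipole:
  ``d(t) = sum_c (r_c - r_m) I_c(t)``, summed over every compartment of every
  neuron.  When each neuron's currents sum to zero the result is exactly
  independent of the expansion point ``r_m``.

Amplitudes are reported in nA*m (1 uA*mm = 1 nA*m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .csd import CSDProfile
from .synthetic import CompartmentCurrentSet

__all__ = ["DipoleSource", "dipole_from_csd", "dipole_from_stc", "orient_from_mesh"]


@dataclass
class DipoleSource:
    """Point dipole: position (mm), unit orientation, amplitude trace (nA*m)."""

    position_mm: np.ndarray  # (3,)
    orientation: np.ndarray  # (3,), unit norm
    amplitude_nam: np.ndarray  # (n_t,)
    dt_ms: float
    r_c_mm: float = 1.5
    provenance: str = "CSD"

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, float)
        self.orientation = np.asarray(self.orientation, float)
        self.amplitude_nam = np.atleast_1d(np.asarray(self.amplitude_nam, float))
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation must be a unit vector")
        if self.r_c_mm <= 0:
            raise ValueError("column radius must be positive")

    def moment_nam(self) -> np.ndarray:
        """(3, n_t) moment vector time series."""
        return self.orientation[:, None] * self.amplitude_nam[None, :]


def dipole_from_csd(
    profile: CSDProfile,
    r_c_mm: float = 1.5,
    z_m_mm: float | None = None,
) -> np.ndarray:
    """Dipole amplitude d_z(t) in nA*m from a CSD depth profile.

    ``z_m_mm`` is the reference depth of the dipole on the profile's z axis
    (default: midpoint of the grid, i.e. the middle of the electrode span).
    Note uA/mm^3 * mm^2 * mm * mm = uA*mm = nA*m, so no unit factor appears.
    """
    if r_c_mm <= 0:
        raise ValueError("column radius must be positive")
    z = profile.z_mm
    if len(z) < 2:
        raise ValueError("CSD grid must have at least 2 points")
    if z_m_mm is None:
        z_m_mm = 0.5 * (z[0] + z[-1])
    if not (z[0] <= z_m_mm <= z[-1]):
        raise ValueError("z_m must lie within the CSD grid")
    integrand = profile.csd_ua_mm3 * (z - z_m_mm)[:, None]
    return math.pi * r_c_mm**2 * np.trapezoid(integrand, z, axis=0)


def dipole_from_stc(
    currents: CompartmentCurrentSet,
    r_m_mm: np.ndarray | None = None,
    *,
    conservation_tol: float = 1e-9,
) -> np.ndarray:
    """(3, n_t) dipole moment in nA*m summed over all compartments.

    Warns if the per-neuron currents do not conserve (the result then depends
    on the expansion point ``r_m_mm``, which defaults to the center of mass of
    the compartment cloud).
    """
    if r_m_mm is None:
        r_m_mm = currents.coords_mm.mean(axis=0)
    r_m_mm = np.asarray(r_m_mm, float)
    if currents.conservation_residual() > conservation_tol:
        warnings.warn(
            "per-neuron transmembrane currents do not sum to zero; the dipole "
            "moment depends on the expansion point"
        )
    disp = currents.coords_mm - r_m_mm[None, :]  # mm
    moment_na_mm = disp.T @ currents.currents_na  # (3, n_t), nA*mm
    return moment_na_mm * 1e-3  # nA*m


def orient_from_mesh(mesh: trimesh.Trimesh, position_mm: np.ndarray,
                     max_dist_mm: float = 1.0) -> np.ndarray:
    """Outward unit normal at the mesh vertex nearest to ``position_mm``.

    The orientation is the area-weighted average of the normals of the
    triangles incident to the nearest vertex (its 1-ring), normalized.
    """
    position_mm = np.asarray(position_mm, float)
    if len(mesh.vertices) == 0:
        raise ValueError("empty mesh")
    d2 = np.einsum("ij,ij->i", mesh.vertices - position_mm, mesh.vertices - position_mm)
    vid = int(np.argmin(d2))
    if math.sqrt(d2[vid]) > max_dist_mm:
        raise ValueError("position is farther than max_dist_mm from every vertex")
    incident = np.where((mesh.faces == vid).any(axis=1))[0]
    areas = mesh.area_faces[incident]
    good = areas > 0
    if not good.any():
        raise ValueError("all incident triangles are degenerate")
    n = (mesh.face_normals[incident[good]] * areas[good, None]).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate incident-normal average")
    return n / norm
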