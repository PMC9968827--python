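"""Agreement metrics for forward solutions and depth-dependence analysis.

Two standard measures compare a candidate forward solution ``yhat`` against a
ground truth ``y``:

* MAG (relative magnitude) = ||yhat|| / ||y||        (ideal 1)
* RDM (relative difference) = || y/||y|| - yhat/||yhat|| ||   (ideal 0, max 2)

Norms are root-sum-square over the chosen axis: time samples for traces,
electrodes for static topographies, or the flattened array for
electrode x time matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import stats

from .dipole import orient_from_mesh

__all__ = [
    "mag",
    "rdm",
    "column_depth",
    "depth_regression",
    "random_column_sites",
    "AgreementReport",
]


def _norm(x: np.ndarray, axis) -> np.ndarray:
    return np.sqrt(np.sum(np.square(x), axis=axis))


def mag(y: np.ndarray, yhat: np.ndarray, axis=None) -> float | np.ndarray:
    """Relative magnitude ||yhat|| / ||y||."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ny = _norm(y, axis)
    if np.any(ny == 0):
        raise ValueError("ground truth is identically zero")
    return _norm(yhat, axis) / ny


def rdm(y: np.ndarray, yhat: np.ndarray, axis=None) -> float | np.ndarray:
    """Relative difference measure between unit-normalized signals (0..2)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ny = _norm(y, axis)
    nh = _norm(yhat, axis)
    if np.any(ny == 0) or np.any(nh == 0):
        raise ValueError("RDM undefined for zero signals")
    if axis is None:
        return float(_norm(y / ny - yhat / nh, None))
    ny = np.expand_dims(ny, axis)
    nh = np.expand_dims(nh, axis)
    return _norm(y / ny - yhat / nh, axis)


def column_depth(scalp_mesh: trimesh.Trimesh, point_mm: np.ndarray) -> float:
    """Shortest distance (mm) from a point to the scalp triangle mesh.

    Exact point-to-mesh distance handling face, edge and vertex cases.
    """
    if len(scalp_mesh.faces) == 0:
        raise ValueError("empty mesh")
    from ._geometry import closest_point_on_mesh

    point = np.atleast_2d(np.asarray(point_mm, float))
    _, dist, _, _ = closest_point_on_mesh(scalp_mesh, point)
    return float(dist[0])


def depth_regression(depths_mm: np.ndarray, metric_values: np.ndarray):
    """OLS of a metric on column depth; returns (slope, intercept, r_squared)."""
    depths = np.asarray(depths_mm, float)
    vals = np.asarray(metric_values, float)
    if len(depths) < 3:
        raise ValueError("need at least 3 locations")
    if np.ptp(depths) == 0:
        raise ValueError("depths are constant; regression undefined")
    if np.ptp(vals) == 0:
        return 0.0, float(vals[0]), 0.0  # constant metric: flat fit, R^2 = 0
    res = stats.linregress(depths, vals)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def random_column_sites(
    cortex_mesh: trimesh.Trimesh,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` distinct mesh vertices (uniform, without replacement).

    Returns (positions (n, 3) mm, outward unit orientations (n, 3)) with
    orientations from the 1-ring area-weighted vertex normals.
    """
    n_vert = len(cortex_mesh.vertices)
    if n_vert == 0:
        raise ValueError("empty mesh")
    if n > n_vert:
        raise ValueError("cannot sample more sites than vertices")
    idx = rng.choice(n_vert, size=n, replace=False)
    positions = np.asarray(cortex_mesh.vertices[idx], float)
    orientations = np.array(
        [orient_from_mesh(cortex_mesh, p, max_dist_mm=np.inf) for p in positions]
    )
    return positions, orientations


@dataclass
class AgreementReport:
    """Per-location RDM/MAG table plus the depth regressions."""

    positions_mm: np.ndarray  # (n, 3)
    depths_mm: np.ndarray  # (n,)
    rdm_values: np.ndarray  # (n,)
    mag_values: np.ndarray  # (n,)
    regressions: dict = field(default_factory=dict)

    @classmethod
    def from_site_metrics(cls, positions_mm, depths_mm, rdm_values, mag_values):
        report = cls(
            positions_mm=np.asarray(positions_mm, float),
            depths_mm=np.asarray(depths_mm, float),
            rdm_values=np.asarray(rdm_values, float),
            mag_values=np.asarray(mag_values, float),
        )
        for name, vals in (("rdm", report.rdm_values), ("mag", report.mag_values)):
            slope, intercept, r2 = depth_regression(report.depths_mm, vals)
            report.regressions[name] = {
                "slope": slope, "intercept": intercept, "r_squared": r2
            }
        return report

    def summary(self) -> dict:
        return {
            "mean_rdm": float(self.rdm_values.mean()),
            "sd_rdm": float(self.rdm_values.std(ddof=1)) if len(self.rdm_values) > 1 else 0.0,
            "mean_mag": float(self.mag_values.mean()),
            "sd_mag": float(self.mag_values.std(ddof=1)) if len(self.mag_values) > 1 else 0.0,
            "regressions": self.regressions,
        }
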