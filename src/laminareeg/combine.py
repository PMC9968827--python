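"""Multi-dipole source configurations ranked against an empirical topography.

Candidate cortical sources (e.g., gyral V4, sulcal V4, LIP, 7a, FEF) each
contribute a modeled scalp map; every non-empty subset of sources defines a
configuration whose map is the electrode-wise sum of its members.  Each
configuration is scored by the Pearson correlation between the empirical map
and the modeled maps pooled over electrodes and recording sessions
(n_electrodes x n_sessions points per correlation).  Negatively correlated
configurations are recorded with R^2 = 0, significance is Bonferroni-corrected
over the number of configurations, and the winner is the configuration with
the largest retained R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .headmodel import ScalpTopography

__all__ = [
    "enumerate_configurations",
    "sum_topographies",
    "difference_topography",
    "rank_against_empirical",
    "ConfigurationRanking",
]


def enumerate_configurations(source_labels: list[str]) -> list[tuple[str, ...]]:
    """All 2^n - 1 non-empty subsets, in deterministic (size, order) order."""
    n = len(source_labels)
    if n < 1:
        raise ValueError("need at least one source label")
    if n > 16:
        raise ValueError("too many sources to enumerate")
    configs: list[tuple[str, ...]] = []
    for size in range(1, n + 1):
        configs.extend(combinations(source_labels, size))
    return configs


def _check_montages(topos: list[ScalpTopography]) -> list[str]:
    labels = topos[0].labels
    for t in topos[1:]:
        if t.labels != labels:
            raise ValueError("montage mismatch between topographies")
    return labels


def sum_topographies(topos: list[ScalpTopography], condition: str | None = None) -> ScalpTopography:
    """Electrode-wise sum of maps sharing one montage."""
    labels = _check_montages(topos)
    total = np.sum([t.values_uv for t in topos], axis=0)
    return ScalpTopography(
        labels, total,
        condition=condition if condition is not None else topos[0].condition,
        dt_ms=topos[0].dt_ms,
    )


def difference_topography(contra: ScalpTopography, ipsi: ScalpTopography) -> ScalpTopography:
    """Contralateral-minus-ipsilateral difference map, tagged 'difference'."""
    labels = _check_montages([contra, ipsi])
    return ScalpTopography(
        labels, contra.values_uv - ipsi.values_uv, condition="difference",
        dt_ms=contra.dt_ms,
    )


@dataclass
class ConfigurationRanking:
    """Sorted scores of all source configurations against the empirical map."""

    configurations: list[tuple[str, ...]]
    pearson_r: np.ndarray  # raw correlation per configuration
    r_squared: np.ndarray  # retained R^2 (0 where r < 0)
    p_values: np.ndarray
    significant: np.ndarray  # Bonferroni at alpha / n_configurations
    n_points: int

    @property
    def order(self) -> np.ndarray:
        """Configuration indices sorted by descending retained R^2."""
        return np.argsort(-self.r_squared, kind="stable")

    @property
    def winner(self) -> tuple[str, ...]:
        return self.configurations[int(self.order[0])]

    def as_records(self) -> list[dict]:
        return [
            {
                "configuration": "+".join(self.configurations[i]),
                "pearson_r": float(self.pearson_r[i]),
                "r_squared": float(self.r_squared[i]),
                "p_value": float(self.p_values[i]),
                "significant": bool(self.significant[i]),
            }
            for i in self.order
        ]


def rank_against_empirical(
    modeled_sessions: dict[str, np.ndarray],
    empirical: ScalpTopography,
    alpha: float = 0.05,
) -> ConfigurationRanking:
    """Score every source configuration against an empirical topography.

    ``modeled_sessions`` maps each source label to an (n_electrodes,
    n_sessions) array of per-session modeled maps on the empirical montage.
    For each configuration the member maps are summed electrode-wise, the
    empirical map is tiled across sessions, and a single Pearson correlation
    is computed over the pooled n_electrodes x n_sessions points.
    """
    labels = list(modeled_sessions)
    emp = np.asarray(empirical.values_uv, float)
    if emp.ndim != 1:
        raise ValueError("empirical topography must be a static map")
    n_e = len(emp)
    shapes = {np.asarray(v).shape for v in modeled_sessions.values()}
    if len(shapes) != 1:
        raise ValueError("per-source session arrays must share one shape")
    shape = shapes.pop()
    if len(shape) != 2 or shape[0] != n_e:
        raise ValueError("session arrays must be (n_electrodes, n_sessions)")
    n_sessions = shape[1]
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    n_points = n_e * n_sessions
    if n_points < 3:
        raise ValueError("fewer than 3 pooled points")
    if np.ptp(emp) == 0:
        raise ValueError("zero-variance empirical topography")

    configs = enumerate_configurations(labels)
    emp_tiled = np.tile(emp[:, None], (1, n_sessions)).ravel()
    r = np.empty(len(configs))
    p = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        model = np.sum([modeled_sessions[lab] for lab in cfg], axis=0).ravel()
        if np.ptp(model) == 0:
            raise ValueError(f"zero-variance model for configuration {cfg}")
        res = stats.pearsonr(emp_tiled, model)
        r[i], p[i] = res.statistic, res.pvalue
    r2 = np.where(r >= 0, r**2, 0.0)  # negative correlations not considered
    significant = (p < alpha / len(configs)) & (r >= 0)
    return ConfigurationRanking(
        configurations=configs,
        pearson_r=r,
        r_squared=r2,
        p_values=p,
        significant=significant,
        n_points=n_points,
    )
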