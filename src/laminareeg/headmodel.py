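"""EEG forward problem for nested piecewise-homogeneous head models.

The scalp potential generated by primary currents inside the brain
compartment is the solution of a Fredholm integral equation of the second
kind over the compartment boundaries (the classic surface-potential
formulation for piecewise-homogeneous volume conductors):

    sigma_bar(r) v(r) = sigma_b V0(r)
        + (1/4 pi) * sum_k (sigma_k^in - sigma_k^out)
          * int_{S_k} v(r') dOmega_r(r')

where V0 is the infinite-medium potential of the primary source and
sigma_bar is the mean of the conductivities on either side of the surface
through r.  It is discretized here with a vertex-collocation, linear-potential
double-layer BEM: the potential is linear over each triangle and the
solid-angle integrals of the linear shape functions are evaluated
analytically (de Munck's construction).  The rank deficiency from the
arbitrary additive constant is removed by deflation, and the low-conductivity
skull layer is handled with the isolated-skull approach when the
skull:brain conductivity ratio is small.

An analytic concentric-sphere series solution is included as an independent
oracle for validating the BEM, and an idealized spherical 10-10/10-20
electrode layout can be projected onto any closed scalp mesh.

Geometry is in mm; currents in nA, dipole moments in nA*m; potentials in
volts (topographies in uV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from ._geometry import closest_point_on_mesh, ray_mesh_farthest_hits, winding_contains
from .dipole import DipoleSource

__all__ = [
    "HeadModel",
    "ElectrodeMontage",
    "ScalpTopography",
    "build_nested_spheres",
    "v0_monopoles",
    "v0_dipole",
    "BemSolver",
    "analytic_multishell",
    "homogeneous_sphere_potential",
    "place_montage",
    "montage_directions",
    "MONTAGE_10_10",
    "MONTAGE_10_20_15",
]

_IP_APPROACH_LIMIT = 0.1  # enable isolated-skull handling below this ratio


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class HeadModel:
    """Nested closed triangulated surfaces, innermost (brain) first.

    ``conductivities`` has length ``len(surfaces) + 1``: entry ``k`` is the
    conductivity of the medium inside surface ``k``; the last entry is the
    medium outside the outermost surface (air, 0 S/m).
    """

    surfaces: list[trimesh.Trimesh]
    conductivities: list[float]

    def __post_init__(self) -> None:
        if len(self.conductivities) != len(self.surfaces) + 1:
            raise ValueError("need len(surfaces) + 1 conductivities")
        if any(s < 0 for s in self.conductivities):
            raise ValueError("conductivities must be non-negative")

    @property
    def sigma_brain(self) -> float:
        return self.conductivities[0]

    @property
    def scalp(self) -> trimesh.Trimesh:
        return self.surfaces[-1]

    def validate(self, n_probe: int = 100) -> None:
        """Check surfaces are closed and properly nested (raises on failure)."""
        for i, s in enumerate(self.surfaces):
            if not s.is_watertight:
                raise ValueError(f"surface {i} is not closed")
        for i in range(len(self.surfaces) - 1):
            inner, outer = self.surfaces[i], self.surfaces[i + 1]
            pts = inner.vertices
            if len(pts) > n_probe:
                idx = np.linspace(0, len(pts) - 1, n_probe).astype(int)
                pts = pts[idx]
            if not winding_contains(outer, pts).all():
                raise ValueError(f"surface {i} is not nested inside surface {i + 1}")


@dataclass
class ElectrodeMontage:
    """Labeled electrode positions (mm) on the scalp surface."""

    labels: list[str]
    positions_mm: np.ndarray  # (n, 3)
    system: str = "custom"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, float)
        if len(self.labels) != len(self.positions_mm):
            raise ValueError("labels and positions must match")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")

    def subset(self, labels: list[str]) -> "ElectrodeMontage":
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in montage: {missing}")
        rows = [index[lab] for lab in labels]
        return ElectrodeMontage(list(labels), self.positions_mm[rows], self.system)


@dataclass
class ScalpTopography:
    """Per-electrode voltages (uV): a static map or a full trace per channel."""

    labels: list[str]
    values_uv: np.ndarray  # (n_e,) or (n_e, n_t)
    condition: str = ""
    dt_ms: float | None = None

    def __post_init__(self) -> None:
        self.values_uv = np.asarray(self.values_uv, float)
        if self.values_uv.shape[0] != len(self.labels):
            raise ValueError("value rows must match electrode count")

    def window_mean(self, t0_ms: float, t1_ms: float) -> "ScalpTopography":
        if self.values_uv.ndim != 2 or self.dt_ms is None:
            raise ValueError("window_mean needs a time-resolved topography")
        t = np.arange(self.values_uv.shape[1]) * self.dt_ms
        mask = (t >= t0_ms) & (t <= t1_ms)
        if not mask.any():
            raise ValueError("empty analysis window")
        return ScalpTopography(
            self.labels, self.values_uv[:, mask].mean(axis=1), self.condition
        )


def build_nested_spheres(
    radii_mm: tuple[float, ...] = (30.0, 35.0, 38.0),
    subdivisions: int = 3,
    conductivities: tuple[float, ...] = (0.33, 0.0063, 0.43, 0.0),
) -> HeadModel:
    """Synthetic macaque-scale head model from nested icospheres.

    A level-L icosphere has 10 * 4**L + 2 vertices per surface.
    """
    radii = np.asarray(radii_mm, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    surfaces = [trimesh.creation.icosphere(subdivisions=subdivisions, radius=r) for r in radii]
    return HeadModel(surfaces=surfaces, conductivities=list(conductivities))


# ---------------------------------------------------------------------------
# infinite-medium (primary source) potentials
# ---------------------------------------------------------------------------


def v0_monopoles(
    positions_mm: np.ndarray,
    currents_na: np.ndarray,
    sigma_b: float,
    field_points_mm: np.ndarray,
    r_min_mm: float = 0.0,
    chunk: int = 8192,
) -> np.ndarray:
    """Infinite-medium potential (V) of point current sources.

    ``currents_na`` may be (n_src,) or (n_src, n_t); the result is
    (n_field,) or (n_field, n_t).  Sources are processed in chunks to bound
    the memory of the distance matrix.
    """
    pos = np.atleast_2d(np.asarray(positions_mm, float))
    fp = np.atleast_2d(np.asarray(field_points_mm, float))
    I = np.asarray(currents_na, float)
    out = None
    for s in range(0, len(pos), chunk):
        dist = np.linalg.norm(fp[:, None, :] - pos[None, s:s + chunk, :], axis=2)
        dist = np.maximum(dist, r_min_mm)
        if np.any(dist == 0):
            raise ValueError("field point coincides with a source")
        w = 1e-6 / (4 * math.pi * sigma_b * dist)  # nA, mm -> V
        part = w @ I[s:s + chunk]
        out = part if out is None else out + part
    return out


def v0_dipole(
    dipole: DipoleSource | tuple[np.ndarray, np.ndarray],
    sigma_b: float,
    field_points_mm: np.ndarray,
) -> np.ndarray:
    """Infinite-medium potential (V) of a point dipole.

    Accepts a DipoleSource (returning (n_field, n_t)) or a
    ``(position_mm, moment_nam)`` pair with a static 3-vector moment.
    """
    if isinstance(dipole, DipoleSource):
        pos = dipole.position_mm
        moment = dipole.moment_nam()  # (3, n_t)
    else:
        pos, moment = dipole
        moment = np.asarray(moment, float).reshape(3, -1)
    fp = np.atleast_2d(np.asarray(field_points_mm, float))
    diff = fp - np.asarray(pos, float)[None, :]
    r3 = np.linalg.norm(diff, axis=1) ** 3
    if np.any(r3 == 0):
        raise ValueError("field point coincides with the dipole")
    lead = diff / r3[:, None]  # 1/mm^2
    out = 1e-3 / (4 * math.pi * sigma_b) * (lead @ moment)  # nA*m, mm -> V
    return out if out.shape[1] > 1 else out[:, 0]


# ---------------------------------------------------------------------------
# analytic linear-collocation element integrals (de Munck construction)
# ---------------------------------------------------------------------------


def _tri_quantities(mesh: trimesh.Trimesh):
    tri_rr = mesh.vertices[mesh.faces]  # (n_tri, 3, 3)
    tri_nn = mesh.face_normals
    tri_area = mesh.area_faces
    return np.asarray(tri_rr, float), np.asarray(tri_nn, float), np.asarray(tri_area, float)


def _beta(rk, nk, rk1, nk1):
    """Edge line-integral coefficients, broadcast over (n_obs, n_tri)."""
    edge = rk1 - rk
    size = np.linalg.norm(edge, axis=-1)
    edge = edge / size[..., None]
    num = nk + np.einsum("...i,...i->...", rk, edge)
    den = nk1 + np.einsum("...i,...i->...", rk1, edge)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(num / den) / size  # bad (in-plane) points are masked later


def _lin_pot_coeff(fros: np.ndarray, tri_rr: np.ndarray, tri_nn: np.ndarray,
                   tri_area: np.ndarray) -> np.ndarray:
    """Analytic integrals of the linear shape functions against the
    solid-angle kernel: omega[i, j, k] is the contribution of vertex k of
    triangle j to the double-layer potential at observation point i.
    """
    # displacement from observation points to triangle corners
    y = tri_rr[None, :, :, :] - fros[:, None, None, :]  # (n_obs, n_tri, 3, 3)
    y1, y2, y3 = y[:, :, 0], y[:, :, 1], y[:, :, 2]
    triple = np.einsum("...i,...i->...", np.cross(y1, y2), y3)
    l1 = np.linalg.norm(y1, axis=-1)
    l2 = np.linalg.norm(y2, axis=-1)
    l3 = np.linalg.norm(y3, axis=-1)
    ss = (
        l1 * l2 * l3
        + np.einsum("...i,...i->...", y1, y2) * l3
        + np.einsum("...i,...i->...", y1, y3) * l2
        + np.einsum("...i,...i->...", y2, y3) * l1
    )
    solids = np.arctan2(triple, ss)  # half the solid angle
    bad = np.abs(solids) < math.pi / 1e6
    safe1 = np.where(bad, 1.0, l1)
    safe2 = np.where(bad, 1.0, l2)
    safe3 = np.where(bad, 1.0, l3)

    b12 = _beta(y1, safe1, y2, safe2)
    b23 = _beta(y2, safe2, y3, safe3)
    b31 = _beta(y3, safe3, y1, safe1)
    vec_omega = (
        (b31 - b12)[..., None] * y1
        + (b12 - b23)[..., None] * y2
        + (b23 - b31)[..., None] * y3
    )

    area2 = 2.0 * tri_area[None, :]
    inv_n2 = 1.0 / (area2 * area2)
    ys = (y1, y2, y3)
    nn = tri_nn[None, :, :]
    omega = np.empty(solids.shape + (3,))
    idx = [0, 1, 2, 0, 2]
    for k in range(3):
        diff = ys[idx[k - 1]] - ys[idx[k + 1]]
        zdots = np.einsum(
            "...i,...i->...", np.cross(ys[idx[k + 1]], ys[idx[k - 1]]), nn
        )
        omega[..., k] = -inv_n2 * (
            area2 * zdots * 2.0 * solids
            - triple * np.einsum("...i,...i->...", diff, vec_omega)
        )
    omega[bad] = 0.0
    return omega


def _vertex_tri_counts(mesh: trimesh.Trimesh) -> np.ndarray:
    return np.bincount(mesh.faces.ravel(), minlength=len(mesh.vertices))


def _correct_auto_elements(mesh: trimesh.Trimesh, mat: np.ndarray) -> None:
    """Improve the diagonal (auto-solid-angle) elements so each row of the
    same-surface block integrates to the full 2*pi solid angle."""
    pi2 = 2.0 * math.pi
    misses = pi2 - mat.sum(axis=1)
    faces = mesh.faces
    n_memb = _vertex_tri_counts(mesh)
    for j, miss in enumerate(misses):
        mat[j, j] = miss / 2.0
        members = np.where((faces == j).any(axis=1))[0]
        share = miss / (4.0 * n_memb[j])
        for t in members:
            for v in faces[t]:
                if v != j:
                    mat[j, v] += share
    return


def _pot_coeff_block(obs_points: np.ndarray, src_mesh: trimesh.Trimesh,
                     self_block: bool, chunk: int = 256) -> np.ndarray:
    """Assemble -sum(omega) for one observation-set / source-surface pair."""
    tri_rr, tri_nn, tri_area = _tri_quantities(src_mesh)
    n_obs = len(obs_points)
    block = np.zeros((n_obs, len(src_mesh.vertices)))
    faces = src_mesh.faces
    obs_ids = np.arange(n_obs)
    for start in range(0, len(faces), chunk):
        sl = slice(start, start + chunk)
        omega = _lin_pot_coeff(obs_points, tri_rr[sl], tri_nn[sl], tri_area[sl])
        tris = faces[sl]
        if self_block:
            skip = obs_ids[:, None, None] == tris[None, :, :]
            omega[skip.any(axis=2)] = 0.0
        for k in range(3):
            np.subtract.at(block.T, tris[:, k], omega[:, :, k].T)
    return block


# ---------------------------------------------------------------------------
# BEM solver
# ---------------------------------------------------------------------------


class BemSolver:
    """Vertex-collocation linear-potential double-layer BEM.

    On construction, assembles the boundary operator, applies deflation, and
    inverts it (with the isolated-skull modification for three-layer models
    whose middle layer is much less conductive than the innermost).  The
    resulting dense solution matrix maps scaled infinite-medium potentials at
    all surface vertices to the surface potentials.
    """

    def __init__(self, model: HeadModel, *, ip_approach: bool | None = None,
                 validate: bool = True):
        if validate:
            model.validate()
        self.model = model
        # internal ordering: outermost first (scalp ... brain)
        surfs = list(model.surfaces[::-1])
        cond = np.asarray(model.conductivities, float)
        sigma_in = cond[:-1][::-1]  # inside each surface, outermost first
        sigma_out = cond[1:][::-1]  # outside each surface, outermost first
        self._nps = [len(s.vertices) for s in surfs]
        n_tot = sum(self._nps)
        offsets = np.cumsum([0] + self._nps)

        denom = sigma_in + sigma_out
        gamma = (sigma_in - sigma_out)[None, :] / denom[:, None]
        self._source_mult = np.repeat(2.0 / denom, self._nps)

        coeff = np.empty((n_tot, n_tot))
        for i, s_obs in enumerate(surfs):
            for j, s_src in enumerate(surfs):
                blk = _pot_coeff_block(
                    np.asarray(s_obs.vertices, float), s_src, self_block=(i == j)
                )
                coeff[offsets[i]:offsets[i + 1], offsets[j]:offsets[j + 1]] = blk
            _correct_auto_elements(
                s_obs, coeff[offsets[i]:offsets[i + 1], offsets[i]:offsets[i + 1]]
            )

        solution = self._multi_solution(coeff.copy(), gamma)
        if len(surfs) == 3 and sigma_in[2] > 0:
            ip_mult = sigma_in[1] / sigma_in[2]  # skull / brain
            use_ip = ip_approach if ip_approach is not None else ip_mult <= _IP_APPROACH_LIMIT
            if use_ip:
                inner = surfs[-1]
                coeff_h = _pot_coeff_block(
                    np.asarray(inner.vertices, float), inner, self_block=True
                )
                _correct_auto_elements(inner, coeff_h)
                ip_solution = self._multi_solution(coeff_h, None, nps=[self._nps[-1]])
                self._ip_modify(solution, ip_solution, ip_mult)
        self._solution = solution
        # permutation mapping model order (innermost first) -> internal
        # order (outermost first): g_internal = g_model[perm]
        nps_in_first = [len(s.vertices) for s in model.surfaces]
        off_in = np.cumsum([0] + nps_in_first)
        perm = []
        for i in range(len(nps_in_first) - 1, -1, -1):
            perm.extend(range(off_in[i], off_in[i + 1]))
        self._perm_in2out = np.asarray(perm)
        self._perm_out2in = np.argsort(self._perm_in2out)

    def _multi_solution(self, solids: np.ndarray, gamma: np.ndarray | None,
                        nps: list[int] | None = None) -> np.ndarray:
        nps = self._nps if nps is None else nps
        n_tot = sum(nps)
        pi2 = 1.0 / (2 * math.pi)
        defl = 1.0 / n_tot
        offsets = np.cumsum([0] + list(nps))
        for i in range(len(nps)):
            for j in range(len(nps)):
                mult = pi2 if gamma is None else pi2 * gamma[i, j]
                sl_i = slice(offsets[i], offsets[i + 1])
                sl_j = slice(offsets[j], offsets[j + 1])
                solids[sl_i, sl_j] = defl - solids[sl_i, sl_j] * mult
        solids += np.eye(n_tot)
        return np.linalg.inv(solids)

    def _ip_modify(self, solution: np.ndarray, ip_solution: np.ndarray,
                   ip_mult: float) -> None:
        """Isolated-skull modification of the inverted operator."""
        n_last = self._nps[-1]
        mult = (1.0 + ip_mult) / ip_mult
        n_before = sum(self._nps[:-1])
        offsets = np.cumsum([0] + self._nps)
        for i in range(len(self._nps)):
            sub = solution[offsets[i]:offsets[i + 1], n_before:]
            sub -= 2 * (sub @ ip_solution)
        solution[n_before:, n_before:] += mult * ip_solution
        solution *= ip_mult

    # -- source terms ------------------------------------------------------

    @property
    def vertices_mm(self) -> np.ndarray:
        """All surface vertices, innermost surface first."""
        return np.concatenate([np.asarray(s.vertices, float) for s in self.model.surfaces])

    def surface_potentials(self, v0_vertices: np.ndarray) -> np.ndarray:
        """Potentials (V) at all surface vertices (innermost-first order).

        ``v0_vertices`` are infinite-medium potentials at the vertices
        returned by :attr:`vertices_mm`, shape (n_vert,) or (n_vert, n_t).
        """
        v0 = np.asarray(v0_vertices, float)
        squeeze = v0.ndim == 1
        g = 4 * math.pi * self.model.sigma_brain * np.atleast_2d(v0.T).T
        g = g.reshape(len(v0), -1)
        rhs = (self._source_mult / (4 * math.pi))[:, None] * g[self._perm_in2out]
        v = (self._solution @ rhs)[self._perm_out2in]
        return v[:, 0] if squeeze else v

    def scalp_interpolator(self, electrode_positions_mm: np.ndarray) -> np.ndarray:
        """(n_e, n_scalp_vertices) barycentric interpolation matrix."""
        scalp = self.model.scalp
        pts = np.atleast_2d(np.asarray(electrode_positions_mm, float))
        _, _, tri_idx, bary = closest_point_on_mesh(scalp, pts)
        W = np.zeros((len(pts), len(scalp.vertices)))
        for r, (ti, w) in enumerate(zip(tri_idx, bary)):
            W[r, scalp.faces[ti]] = w
        return W

    def electrode_potentials(
        self,
        electrode_positions_mm: np.ndarray,
        v0_vertices: np.ndarray,
        *,
        average_reference: bool = True,
    ) -> np.ndarray:
        """Potentials (V) at scalp electrodes given V0 at all vertices."""
        v = self.surface_potentials(v0_vertices)
        n_scalp = len(self.model.scalp.vertices)
        v_scalp = v[-n_scalp:]
        W = self.scalp_interpolator(electrode_positions_mm)
        ve = W @ v_scalp
        if average_reference:
            ve = ve - ve.mean(axis=0, keepdims=True)
        return ve

    def forward_dipole(
        self,
        dipole: DipoleSource,
        electrode_positions_mm: np.ndarray,
        *,
        average_reference: bool = True,
    ) -> np.ndarray:
        """Electrode potentials (V) for a dipole source; (n_e, n_t)."""
        v0 = v0_dipole(dipole, self.model.sigma_brain, self.vertices_mm)
        return self.electrode_potentials(
            electrode_positions_mm, v0, average_reference=average_reference
        )

    def forward_monopoles(
        self,
        positions_mm: np.ndarray,
        currents_na: np.ndarray,
        electrode_positions_mm: np.ndarray,
        *,
        average_reference: bool = True,
    ) -> np.ndarray:
        """Electrode potentials (V) for point current sources (compartments)."""
        v0 = v0_monopoles(positions_mm, currents_na, self.model.sigma_brain,
                          self.vertices_mm)
        return self.electrode_potentials(
            electrode_positions_mm, v0, average_reference=average_reference
        )


# ---------------------------------------------------------------------------
# analytic concentric-sphere oracle
# ---------------------------------------------------------------------------


def _legendre_terms(x: np.ndarray, n_max: int):
    """P_n(x) and P_n^1(x) for n = 1..n_max (Condon-Shortley phase),
    via the standard three-term recurrences."""
    x = np.asarray(x, float)
    P = np.zeros((n_max + 1,) + x.shape)
    P[0] = 1.0
    if n_max >= 1:
        P[1] = x
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
    s = -np.sqrt(np.clip(1.0 - x * x, 0.0, None))  # includes CS phase
    P1 = np.zeros_like(P)
    if n_max >= 1:
        P1[1] = s
    if n_max >= 2:
        P1[2] = 3.0 * x * s
    for n in range(2, n_max):
        P1[n + 1] = ((2 * n + 1) * x * P1[n] - (n + 1) * P1[n - 1]) / n
    return P[1:], P1[1:]


def _shell_radial_factors(radii_norm: np.ndarray, conductivities: np.ndarray,
                          n: int) -> tuple[float, float]:
    """Solve the per-degree radial boundary problem.

    Returns (t_rad, t_tan): the scalp-surface value of the harmonic of degree
    n per unit source coefficient c_n (the coefficient of r^-(n+1) in the
    innermost layer).  Identical for both dipole components.
    """
    L = len(radii_norm)
    # unknowns: A_1, (A_j, B_j) for j = 2..L
    m = 2 * L - 1
    A = np.zeros((m, m))
    b = np.zeros(m)

    def col_A(j):  # layer index j = 1..L
        return 0 if j == 1 else 1 + 2 * (j - 2)

    def col_B(j):
        return 2 + 2 * (j - 2)

    row = 0
    for j in range(1, L):  # interface between layer j and j+1 at radii_norm[j-1]
        a = radii_norm[j - 1]
        # continuity of V
        A[row, col_A(j)] += a**n
        if j > 1:
            A[row, col_B(j)] += a ** (-(n + 1))
        A[row, col_A(j + 1)] -= a**n
        A[row, col_B(j + 1)] -= a ** (-(n + 1))
        if j == 1:
            b[row] = -(a ** (-(n + 1)))  # particular term c_n / r^(n+1)
        row += 1
        # continuity of sigma dV/dr
        sj, sj1 = conductivities[j - 1], conductivities[j]
        A[row, col_A(j)] += sj * n * a ** (n - 1)
        if j > 1:
            A[row, col_B(j)] += sj * (-(n + 1)) * a ** (-(n + 2))
        A[row, col_A(j + 1)] -= sj1 * n * a ** (n - 1)
        A[row, col_B(j + 1)] -= sj1 * (-(n + 1)) * a ** (-(n + 2))
        if j == 1:
            b[row] = -sj * (-(n + 1)) * a ** (-(n + 2))
        row += 1
    # outer boundary: no normal current into air
    aL = radii_norm[-1]
    A[row, col_A(L)] = n * aL ** (n - 1)
    if L > 1:
        A[row, col_B(L)] = -(n + 1) * aL ** (-(n + 2))
        sol = np.linalg.solve(A, b)
        vL = sol[col_A(L)] * aL**n + sol[col_B(L)] * aL ** (-(n + 1))
    else:
        b[row] = (n + 1) * aL ** (-(n + 2))
        sol = np.linalg.solve(A[: 1, : 1], b[:1])
        vL = sol[0] * aL**n + aL ** (-(n + 1))
    return vL


def analytic_multishell(
    radii_mm: np.ndarray,
    conductivities: np.ndarray,
    dipole_position_mm: np.ndarray,
    dipole_moment_nam: np.ndarray,
    electrode_directions: np.ndarray,
    n_terms: int = 100,
) -> tuple[np.ndarray, float]:
    """Legendre-series scalp potential (V) of a dipole in concentric spheres.

    ``conductivities`` gives the medium inside each radius (outside is air).
    Electrodes sit on the outermost sphere along the given unit directions.
    Returns ``(potentials, truncation_bound)`` where the bound is the max
    absolute last-degree term over electrodes.
    """
    radii = np.asarray(radii_mm, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    cond = np.asarray(conductivities, float)
    if len(cond) != len(radii):
        raise ValueError("need one conductivity per shell")
    r0 = np.asarray(dipole_position_mm, float)
    m = np.asarray(dipole_moment_nam, float)
    b = np.linalg.norm(r0)
    if b >= radii[0]:
        raise ValueError("dipole must lie strictly inside the innermost sphere")
    aL = radii[-1]
    radii_norm = radii / aL
    beta = b / aL

    if b / radii[0] < 1e-12:
        rhat = np.array([0.0, 0.0, 1.0])
    else:
        rhat = r0 / b
    m_r = float(m @ rhat)
    m_t_vec = m - m_r * rhat
    p_t = float(np.linalg.norm(m_t_vec))
    that = m_t_vec / p_t if p_t > 0 else np.zeros(3)

    dirs = np.atleast_2d(np.asarray(electrode_directions, float))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    cos_th = np.clip(dirs @ rhat, -1.0, 1.0)
    perp = dirs - cos_th[:, None] * rhat[None, :]
    pnorm = np.linalg.norm(perp, axis=1)
    cos_phi = np.where(pnorm > 1e-15, (perp @ that) / np.where(pnorm > 0, pnorm, 1.0), 0.0)

    Pn, Pn1 = _legendre_terms(cos_th, n_terms)
    sigma1 = cond[0]
    scale = 1e-3 / (4 * math.pi * sigma1 * aL**2)  # nA*m, mm -> V

    V = np.zeros(len(dirs))
    last = np.zeros(len(dirs))
    for n in range(1, n_terms + 1):
        t_n = _shell_radial_factors(radii_norm, cond, n)
        c_rad = m_r * n * beta ** (n - 1)
        c_tan = -p_t * beta ** (n - 1)
        term = scale * t_n * (c_rad * Pn[n - 1] + c_tan * Pn1[n - 1] * cos_phi)
        V += term
        last = term
    return V, float(np.max(np.abs(last)))


def homogeneous_sphere_potential(
    radius_mm: float,
    sigma: float,
    dipole_position_mm: np.ndarray,
    dipole_moment_nam: np.ndarray,
    electrode_directions: np.ndarray,
) -> np.ndarray:
    """Closed-form surface potential (V) of a dipole in a homogeneous sphere.

    Obtained by summing the Legendre series in closed form (generating
    functions); used as an independent check of the series oracle.
    """
    a = radius_mm
    r0 = np.asarray(dipole_position_mm, float)
    m = np.asarray(dipole_moment_nam, float)
    b = np.linalg.norm(r0)
    f = b / a
    rhat = r0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    m_r = float(m @ rhat)
    m_t_vec = m - m_r * rhat
    p_t = float(np.linalg.norm(m_t_vec))
    that = m_t_vec / p_t if p_t > 0 else np.zeros(3)

    dirs = np.atleast_2d(np.asarray(electrode_directions, float))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    x = np.clip(dirs @ rhat, -1.0, 1.0)
    perp = dirs - x[:, None] * rhat[None, :]
    pnorm = np.linalg.norm(perp, axis=1)
    cos_phi = np.where(pnorm > 1e-15, (perp @ that) / np.where(pnorm > 0, pnorm, 1.0), 0.0)
    sin_th = np.sqrt(np.clip(1 - x * x, 0.0, None))

    g = np.sqrt(1.0 - 2.0 * f * x + f * f)
    scale = 1e-3 / (4 * math.pi * sigma * a**2)
    v_rad = m_r * (2.0 * (x - f) / g**3 + (1.0 / g - 1.0) / f) if f > 0 else m_r * 3.0 * x
    with np.errstate(divide="ignore", invalid="ignore"):
        tan_series = 2.0 / g**3 + ((f - x) / g + x) / (f * (1.0 - x * x))
    tan_series = np.where(sin_th > 1e-12, tan_series, 0.0)
    v_tan = p_t * sin_th * cos_phi * tan_series if f > 0 else p_t * 3.0 * sin_th * cos_phi
    return scale * (v_rad + v_tan)


# ---------------------------------------------------------------------------
# electrode montages
# ---------------------------------------------------------------------------


def _slerp(u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    omega = math.acos(float(np.clip(u @ v, -1.0, 1.0)))
    if omega < 1e-12:
        return u
    return (math.sin((1 - t) * omega) * u + math.sin(t * omega) * v) / math.sin(omega)


def _build_unit_sphere_1010() -> dict[str, np.ndarray]:
    """Idealized spherical 10-10 layout (61 labels), Cz at the apex.

    Midline and ear-to-ear contours follow exact 10% arc steps; the outer
    ring lies on the 10%-elevation circle; intermediate rows interpolate along
    geodesics between the midline and ring electrodes of the same row.
    """
    pos: dict[str, np.ndarray] = {}

    def midline(frac):  # 0 = nasion, 1 = inion, over the vertex
        a = math.pi * frac
        return np.array([0.0, math.cos(a), math.sin(a)])

    for lab, f in zip(
        ["Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"],
        [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    ):
        pos[lab] = midline(f)

    def coronal(frac):  # 0 = left ear, 1 = right ear, over the vertex
        a = math.pi * frac
        return np.array([-math.cos(a), 0.0, math.sin(a)])

    for lab, f in zip(
        ["T7", "C5", "C3", "C1", "C2", "C4", "C6", "T8"],
        [0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9],
    ):
        pos[lab] = coronal(f)

    z = math.sin(0.1 * math.pi)
    rho = math.cos(0.1 * math.pi)

    def ring(frac, side):  # 0 = front (Fpz), 1 = back (Oz); side -1 left, +1 right
        a = math.pi * frac
        return np.array([side * rho * math.sin(a), rho * math.cos(a), z])

    ring_labels = ["Fp", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O"]
    for f, lab in zip([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9], ring_labels):
        left = lab if lab not in ("Fp", "O") else {"Fp": "Fp1", "O": "O1"}[lab]
        pos[left] = ring(f, -1.0)
        right = left.replace("7", "8").replace("1", "2")
        pos[right] = ring(f, +1.0)

    rows = {
        "AF": (["AF3"], [0.5]),
        "F": (["F1", "F3", "F5"], [0.25, 0.5, 0.75]),
        "FC": (["FC1", "FC3", "FC5"], [0.25, 0.5, 0.75]),
        "C": ([], []),  # already on the coronal contour
        "CP": (["CP1", "CP3", "CP5"], [0.25, 0.5, 0.75]),
        "P": (["P1", "P3", "P5"], [0.25, 0.5, 0.75]),
        "PO": (["PO3"], [0.5]),
    }
    ring_of = {"AF": "AF7", "F": "F7", "FC": "FT7", "CP": "TP7", "P": "P7", "PO": "PO7"}
    mid_of = {"AF": "AFz", "F": "Fz", "FC": "FCz", "CP": "CPz", "P": "Pz", "PO": "POz"}
    for row, (labels, fracs) in rows.items():
        if not labels:
            continue
        u, v = pos[mid_of[row]], pos[ring_of[row]]
        for lab, f in zip(labels, fracs):
            p = _slerp(u, v, f)
            pos[lab] = p / np.linalg.norm(p)
            mirrored = lab[:-1] + str(int(lab[-1]) + 1)
            pm = pos[lab].copy()
            pm[0] = -pm[0]
            pos[mirrored] = pm
    return pos


_UNIT_1010 = _build_unit_sphere_1010()
MONTAGE_10_10: list[str] = sorted(_UNIT_1010.keys())
# the 15-electrode clinical subset (FpFz is the position midway between
# Fpz and Fz on the midline, i.e. AFz)
MONTAGE_10_20_15: list[str] = [
    "FpFz", "Fpz", "F3", "F4", "Fz", "Cz", "C3", "C4", "Pz",
    "P5", "P6", "POz", "O1", "O2", "Oz",
]
_ALIASES = {"FpFz": "AFz"}


def montage_directions(labels: list[str]) -> np.ndarray:
    """Unit-sphere directions for standard 10-10 labels (aliases resolved)."""
    out = []
    for lab in labels:
        key = _ALIASES.get(lab, lab)
        if key not in _UNIT_1010:
            raise KeyError(f"unknown electrode label {lab!r}")
        out.append(_UNIT_1010[key])
    return np.asarray(out)


def place_montage(scalp_mesh: trimesh.Trimesh, system: str = "10-10",
                  labels: list[str] | None = None,
                  center_mm: np.ndarray | None = None) -> ElectrodeMontage:
    """Project a standard spherical layout radially onto the scalp mesh.

    ``system`` is ``"10-10"`` (61 sites), ``"10-20"`` (the 15-electrode
    subset), or ``"custom"`` with explicit ``labels``.
    """
    if not scalp_mesh.is_watertight:
        raise ValueError("scalp mesh must be closed")
    if system == "10-10":
        labels = MONTAGE_10_10
    elif system == "10-20":
        labels = MONTAGE_10_20_15
    elif system == "custom":
        if not labels:
            raise ValueError("custom system needs labels")
    else:
        raise ValueError(f"unknown montage system {system!r}")
    dirs = montage_directions(labels)
    center = np.asarray(
        scalp_mesh.centroid if center_mm is None else center_mm, float
    )
    positions = ray_mesh_farthest_hits(scalp_mesh, center, dirs)
    return ElectrodeMontage(list(labels), positions, system)
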