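"""Synthetic cortical-column generator: reduced pyramidal cells and their currents.

Two populations of unconnected pyramidal cells (supragranular L3 and
infragranular L5) are placed uniformly inside a cylindrical column and driven
by brief noisy current pulses injected at the soma.  Each cell is a passive
ball-and-stick cable (soma plus apical trunk); suprathreshold somatic
depolarization triggers stereotyped somatic Na transients, and - for L5 cells
only - a sufficiently strong stimulus triggers a prolonged dendritic Ca
transient injected at the distal apical compartments.  All injected currents
are solved through the cable, so the per-neuron transmembrane currents sum to
zero at every time sample (no spurious monopoles in downstream potentials).

Coordinates are in mm in a "column frame": the pia lies at z = 0 and z
decreases with depth, so supragranular positions have larger z than
infragranular ones.  Currents are reported in nA, time in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import lu_factor, lu_solve

__all__ = [
    "ReducedNeuron",
    "PopulationSpec",
    "StimulusSpec",
    "CompartmentCurrentSet",
    "build_reduced_cell",
    "place_population",
    "simulate_population",
]

# geometry defaults (um)
_L3_SOMA_DEPTH_UM = 712.5  # middle of the 675-750 um band
_L5_SOMA_DEPTH_UM = 1500.0  # middle of the 1250-1750 um band
_L3_TRUNK_UM = 600.0
_L5_TRUNK_UM = 1500.0
_L3_N_TRUNK = 10
_L5_N_TRUNK = 20


@dataclass
class ReducedNeuron:
    """A reduced multicompartment pyramidal cell.

    Compartments form a rooted tree (``parents[0] == -1``; every other parent
    index precedes its child).  Geometry is in mm; membrane parameters use
    the conventional units uF/cm^2, Ohm*cm^2 and Ohm*cm.
    """

    centers_mm: np.ndarray  # (n, 3)
    lengths_mm: np.ndarray  # (n,)
    radii_mm: np.ndarray  # (n,)
    parents: np.ndarray  # (n,) int, -1 for the root (soma)
    label: str = "L3"
    cm_uf_cm2: float = 1.0
    rm_ohm_cm2: float = 10000.0
    ra_ohm_cm: float = 150.0

    def __post_init__(self) -> None:
        self.centers_mm = np.asarray(self.centers_mm, dtype=float)
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        n = len(self.lengths_mm)
        if self.centers_mm.shape != (n, 3):
            raise ValueError("centers_mm must have shape (n, 3)")
        if np.any(self.lengths_mm <= 0) or np.any(self.radii_mm <= 0):
            raise ValueError("compartment lengths and radii must be positive")
        if self.parents[0] != -1 or np.any(self.parents[1:] >= np.arange(1, n)):
            raise ValueError("compartments must form a rooted tree (parent < child)")
        if self.cm_uf_cm2 <= 0 or self.rm_ohm_cm2 <= 0 or self.ra_ohm_cm <= 0:
            raise ValueError("membrane parameters must be positive")

    @property
    def n_compartments(self) -> int:
        return len(self.lengths_mm)

    def translated(self, offset_mm: np.ndarray) -> "ReducedNeuron":
        return replace(self, centers_mm=self.centers_mm + np.asarray(offset_mm, float))

    def geometry_key(self) -> bytes:
        """Hashable signature of electrotonic structure (positions excluded)."""
        rel = self.centers_mm - self.centers_mm[0]
        return b"|".join(
            [
                self.label.encode(),
                rel.tobytes(),
                self.lengths_mm.tobytes(),
                self.radii_mm.tobytes(),
                self.parents.tobytes(),
                np.array([self.cm_uf_cm2, self.rm_ohm_cm2, self.ra_ohm_cm]).tobytes(),
            ]
        )


@dataclass
class PopulationSpec:
    """Layout of the simulated column (counts, radius, soma depth bands in um)."""

    n_l3: int = 2200
    n_l5: int = 1000
    column_radius_mm: float = 1.5
    l3_band_um: tuple[float, float] = (675.0, 750.0)
    l5_band_um: tuple[float, float] = (1250.0, 1750.0)

    def __post_init__(self) -> None:
        if self.n_l3 < 0 or self.n_l5 < 0:
            raise ValueError("population counts must be non-negative")
        if self.column_radius_mm <= 0:
            raise ValueError("column radius must be positive")
        for lo, hi in (self.l3_band_um, self.l5_band_um):
            if not (0 <= lo < hi):
                raise ValueError("depth bands must satisfy 0 <= lo < hi")
        if self.l3_band_um[1] > self.l5_band_um[0]:
            raise ValueError("L3 and L5 soma bands must not overlap")


@dataclass
class StimulusSpec:
    """Somatic current pulse: 30 ms square pulse with Gaussian amplitude."""

    mean_na: float = 1.90
    sd_na: float = 0.3
    duration_ms: float = 30.0
    onset_window_ms: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if self.sd_na < 0:
            raise ValueError("amplitude SD must be non-negative")
        lo, hi = self.onset_window_ms
        if not (0 <= lo <= hi):
            raise ValueError("onset window must satisfy 0 <= lo <= hi")


@dataclass
class CompartmentCurrentSet:
    """Transmembrane currents of every compartment of every neuron.

    ``coords_mm`` stacks compartment centers of all neurons; ``neuron_index``
    maps each row to its neuron.  Currents are in nA with sources (current
    leaving the cell) positive.
    """

    coords_mm: np.ndarray  # (N, 3)
    currents_na: np.ndarray  # (N, n_t)
    dt_ms: float
    neuron_index: np.ndarray  # (N,) int
    labels: list[str]  # per neuron
    meta: dict = field(default_factory=dict)

    @property
    def n_timepoints(self) -> int:
        return self.currents_na.shape[1]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_ms

    @property
    def n_neurons(self) -> int:
        return len(self.labels)

    def conservation_residual(self) -> float:
        """max over neurons and t of |sum_c I_c| relative to max |I|."""
        scale = float(np.max(np.abs(self.currents_na), initial=0.0))
        if scale == 0.0:
            return 0.0
        worst = 0.0
        for i in range(self.n_neurons):
            rows = self.neuron_index == i
            worst = max(worst, float(np.max(np.abs(self.currents_na[rows].sum(axis=0)))))
        return worst / scale

    def subset(self, neuron_ids: np.ndarray) -> "CompartmentCurrentSet":
        neuron_ids = np.asarray(neuron_ids, int)
        rows = np.isin(self.neuron_index, neuron_ids)
        remap = {int(j): k for k, j in enumerate(neuron_ids)}
        return CompartmentCurrentSet(
            coords_mm=self.coords_mm[rows],
            currents_na=self.currents_na[rows],
            dt_ms=self.dt_ms,
            neuron_index=np.array([remap[int(j)] for j in self.neuron_index[rows]]),
            labels=[self.labels[int(j)] for j in neuron_ids],
            meta=dict(self.meta, subset=True),
        )


def build_reduced_cell(
    class_label: str,
    *,
    soma_depth_um: float | None = None,
    trunk_length_um: float | None = None,
    n_trunk: int | None = None,
    soma_diameter_um: float | None = None,
    trunk_diameter_um: float | None = None,
) -> ReducedNeuron:
    """Build an unpositioned (axis at x=y=0) reduced pyramidal cell.

    L3 default: soma + 10-compartment apical stick of 600 um.
    L5 default: soma + 20-compartment apical trunk of 1500 um whose tip
    reaches the pia when the soma sits at its default depth.
    """
    if class_label == "L3":
        soma_depth = _L3_SOMA_DEPTH_UM if soma_depth_um is None else soma_depth_um
        trunk = _L3_TRUNK_UM if trunk_length_um is None else trunk_length_um
        n_tr = _L3_N_TRUNK if n_trunk is None else n_trunk
        soma_d = 20.0 if soma_diameter_um is None else soma_diameter_um
        trunk_d = 3.0 if trunk_diameter_um is None else trunk_diameter_um
    elif class_label == "L5":
        soma_depth = _L5_SOMA_DEPTH_UM if soma_depth_um is None else soma_depth_um
        trunk = _L5_TRUNK_UM if trunk_length_um is None else trunk_length_um
        n_tr = _L5_N_TRUNK if n_trunk is None else n_trunk
        soma_d = 25.0 if soma_diameter_um is None else soma_diameter_um
        trunk_d = 4.0 if trunk_diameter_um is None else trunk_diameter_um
    else:
        raise ValueError(f"unknown cell class {class_label!r} (expected 'L3' or 'L5')")
    if trunk <= 0 or soma_d <= 0 or trunk_d <= 0 or n_tr < 1:
        raise ValueError("geometry values must be positive")

    soma_len_um = soma_d  # soma modeled as an equal-diameter cylinder
    seg_um = trunk / n_tr
    z_soma = -soma_depth / 1000.0  # mm, pia at z = 0
    centers = [np.array([0.0, 0.0, z_soma])]
    lengths = [soma_len_um / 1000.0]
    radii = [soma_d / 2000.0]
    parents = [-1]
    z_top_of_parent = z_soma + soma_len_um / 2000.0
    for k in range(n_tr):
        z_c = z_top_of_parent + (k + 0.5) * seg_um / 1000.0
        centers.append(np.array([0.0, 0.0, z_c]))
        lengths.append(seg_um / 1000.0)
        radii.append(trunk_d / 2000.0)
        parents.append(k)  # previous compartment
    return ReducedNeuron(
        centers_mm=np.array(centers),
        lengths_mm=np.array(lengths),
        radii_mm=np.array(radii),
        parents=np.array(parents),
        label=class_label,
    )


def place_population(
    spec: PopulationSpec, rng: np.random.Generator
) -> list[ReducedNeuron]:
    """Place L3 then L5 template cells uniformly in the column.

    Soma (x, y) is uniform over the disk of the column radius; soma depth is
    uniform within the class band.  Deterministic for a fixed generator state.
    """
    neurons: list[ReducedNeuron] = []
    for label, n, band in (
        ("L3", spec.n_l3, spec.l3_band_um),
        ("L5", spec.n_l5, spec.l5_band_um),
    ):
        template = build_reduced_cell(label)
        r = spec.column_radius_mm * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0.0, 2 * math.pi, size=n)
        depth = rng.uniform(band[0], band[1], size=n) / 1000.0  # mm
        default_depth = -template.centers_mm[0, 2]
        for i in range(n):
            offset = np.array(
                [r[i] * math.cos(theta[i]), r[i] * math.sin(theta[i]),
                 default_depth - depth[i]]
            )
            neurons.append(template.translated(offset))
    return neurons


# ---------------------------------------------------------------------------
# passive cable machinery
# ---------------------------------------------------------------------------


def _cable_matrices(neuron: ReducedNeuron):
    """Capacitance (F), membrane conductance (S) and axial Laplacian (S)."""
    n = neuron.n_compartments
    L_m = neuron.lengths_mm * 1e-3
    r_m = neuron.radii_mm * 1e-3
    area = 2 * math.pi * r_m * L_m  # lateral area, m^2
    cm = neuron.cm_uf_cm2 * 1e-2  # F/m^2
    rm = neuron.rm_ohm_cm2 * 1e-4  # Ohm*m^2
    ra = neuron.ra_ohm_cm * 1e-2  # Ohm*m
    C = cm * area
    G = area / rm
    # half axial resistances, center to end of each compartment
    r_half = ra * (L_m / 2.0) / (math.pi * r_m**2)
    lap = np.zeros((n, n))
    for child in range(1, n):
        p = neuron.parents[child]
        g = 1.0 / (r_half[child] + r_half[p])
        lap[child, child] -= g
        lap[p, p] -= g
        lap[child, p] += g
        lap[p, child] += g
    return C, G, lap


def _solve_cable(
    neuron: ReducedNeuron,
    inj_amps: np.ndarray,  # (n_comp, n_t) injected current in A
    dt_ms: float,
):
    """Crank-Nicolson solve; returns (V volts (n_comp, n_t), I_trans A).

    The transmembrane current of compartment c is evaluated as the net axial
    influx sum_j g_cj (V_j - V_c), which books injected currents as membrane
    currents and makes the per-neuron sum vanish identically.
    """
    C, G, lap = _cable_matrices(neuron)
    n, n_t = inj_amps.shape
    dt = dt_ms * 1e-3
    A = np.diag(C / dt + G / 2.0) - lap / 2.0
    B = np.diag(C / dt - G / 2.0) + lap / 2.0
    lu = lu_factor(A)
    V = np.zeros((n, n_t))
    for k in range(1, n_t):
        rhs = B @ V[:, k - 1] + 0.5 * (inj_amps[:, k] + inj_amps[:, k - 1])
        V[:, k] = lu_solve(lu, rhs)
    return V, lap @ V


def _shift_add(out: np.ndarray, kernel: np.ndarray, shift: int, scale: float) -> None:
    """out[:, shift:] += scale * kernel[:, : n_t - shift] (in place)."""
    n_t = out.shape[1]
    if shift >= n_t or scale == 0.0:
        return
    out[:, shift:] += scale * kernel[:, : n_t - shift]


def _na_waveform(dt_ms: float, amp_na: float = 3.0, width_ms: float = 2.0) -> np.ndarray:
    t = np.arange(0.0, width_ms, dt_ms)
    return amp_na * np.sin(2 * math.pi * t / width_ms)  # zero-net-charge biphasic


def _ca_waveform(dt_ms: float, amp_na: float = 2.0, width_ms: float = 40.0,
                 peak_ms: float = 10.0) -> np.ndarray:
    t = np.arange(0.0, width_ms, dt_ms)
    rise = np.clip(t / peak_ms, 0.0, 1.0)
    fall = np.clip((width_ms - t) / (width_ms - peak_ms), 0.0, 1.0)
    return amp_na * np.minimum(rise, fall)  # triangular inward transient


class _ClassKernels:
    """Precomputed cable responses for one cell geometry.

    The reduced model is linear apart from event triggering, so population
    responses are exact superpositions of these kernels, scaled and shifted
    per neuron.
    """

    def __init__(self, neuron: ReducedNeuron, stim: StimulusSpec, dt_ms: float,
                 n_t: int, n_distal: int = 3):
        self.dt_ms = dt_ms
        n = neuron.n_compartments
        # 1 nA pulse at the soma starting at t = 0
        inj = np.zeros((n, n_t))
        n_pulse = max(1, int(round(stim.duration_ms / dt_ms)))
        inj[0, :n_pulse] = 1e-9
        V, I = _solve_cable(neuron, inj, dt_ms)
        self.pulse_currents_na = I * 1e9
        self.soma_v_unit_mv = V[0] * 1e3  # mV per nA of stimulus

        # somatic Na transient (unit waveform amplitude = the default waveform)
        wave_na = _na_waveform(dt_ms)
        inj = np.zeros((n, n_t))
        inj[0, : len(wave_na)] = wave_na * 1e-9
        _, I = _solve_cable(neuron, inj, dt_ms)
        self.na_currents_na = I * 1e9

        # distal Ca transient (L5): spread over the distal n_distal compartments
        wave_ca = _ca_waveform(dt_ms)
        inj = np.zeros((n, n_t))
        distal = list(range(max(1, n - n_distal), n))
        for c in distal:
            inj[c, : len(wave_ca)] = wave_ca * 1e-9 / len(distal)
        _, I = _solve_cable(neuron, inj, dt_ms)
        self.ca_currents_na = I * 1e9


def simulate_population(
    neurons: list[ReducedNeuron],
    stim: StimulusSpec,
    rng: np.random.Generator,
    *,
    duration_ms: float = 120.0,
    dt_ms: float = 0.1,
    events: bool = True,
    na_threshold_mv: float = 20.0,
    na_refractory_ms: float = 5.0,
    ca_threshold_na: float = 2.0,
) -> CompartmentCurrentSet:
    """Simulate the population response to the noisy somatic current pulse.

    Each neuron draws an amplitude ``mean + sd * z`` (z standard normal) and a
    uniform onset in the stimulus window.  Na events fire whenever the passive
    somatic depolarization exceeds ``na_threshold_mv`` (with a refractory
    interval); L5 cells whose stimulus amplitude exceeds ``ca_threshold_na``
    additionally receive one distal Ca transient 10 ms after stimulus onset.
    A larger population mean therefore gives a non-decreasing expected number
    of Ca events.
    """
    if not neurons:
        raise ValueError("empty population")
    if dt_ms > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    lo, hi = stim.onset_window_ms
    if hi + stim.duration_ms + 60.0 > duration_ms:
        raise ValueError("duration must cover onset window + pulse + 60 ms tail")

    n_t = int(round(duration_ms / dt_ms)) + 1
    n_neurons = len(neurons)
    z = rng.standard_normal(n_neurons)
    amplitudes = stim.mean_na + stim.sd_na * z
    onsets_ms = rng.uniform(lo, hi, size=n_neurons)
    onset_idx = np.round(onsets_ms / dt_ms).astype(int)

    kernels: dict[bytes, _ClassKernels] = {}
    offsets = np.concatenate([[0], np.cumsum([nr.n_compartments for nr in neurons])])
    total = offsets[-1]
    coords = np.concatenate([nr.centers_mm for nr in neurons], axis=0)
    currents = np.zeros((total, n_t))
    neuron_index = np.repeat(np.arange(n_neurons), [nr.n_compartments for nr in neurons])

    na_counts = np.zeros(n_neurons, int)
    ca_counts = np.zeros(n_neurons, int)
    refr = max(1, int(round(na_refractory_ms / dt_ms)))

    for i, nr in enumerate(neurons):
        key = nr.geometry_key()
        if key not in kernels:
            kernels[key] = _ClassKernels(nr, stim, dt_ms, n_t)
        ker = kernels[key]
        block = currents[offsets[i] : offsets[i + 1]]
        amp, shift = float(amplitudes[i]), int(onset_idx[i])
        _shift_add(block, ker.pulse_currents_na, shift, amp)
        if not events or amp == 0.0:
            continue
        v_soma = amp * ker.soma_v_unit_mv  # passive somatic response, mV
        above = v_soma >= na_threshold_mv
        t_idx = 0
        while t_idx < n_t - shift:
            if above[t_idx]:
                _shift_add(block, ker.na_currents_na, shift + t_idx, 1.0)
                na_counts[i] += 1
                t_idx += refr
            else:
                t_idx += 1
        if nr.label == "L5" and amp >= ca_threshold_na:
            ca_shift = shift + int(round(10.0 / dt_ms))
            _shift_add(block, ker.ca_currents_na, ca_shift, 1.0)
            ca_counts[i] += 1

    return CompartmentCurrentSet(
        coords_mm=coords,
        currents_na=currents,
        dt_ms=dt_ms,
        neuron_index=neuron_index,
        labels=[nr.label for nr in neurons],
        meta={
            "amplitudes_na": amplitudes,
            "onsets_ms": onsets_ms,
            "na_counts": na_counts,
            "ca_counts": ca_counts,
            "stimulus": stim,
            "events": events,
        },
    )
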