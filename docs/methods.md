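# Methods

This note documents the models, numerical choices, and limitations behind
`laminareeg`. Units throughout: mm, ms, nA, mV (LFP), µA/mm³ (CSD),
nA·m (dipole moment), V/µV (EEG), S/m (conductivity).

## Reduced-neuron column simulator (`synthetic`)

The simulator produces ground-truth compartment transmembrane currents for
two populations of unconnected pyramidal cells in a cylindrical column
(default 3 mm diameter). It deliberately replaces detailed reconstructed
morphologies with passive ball-and-stick reductions plus stereotyped event
currents: the goal is to preserve the *laminar sink/source geometry* that the
downstream CSD → dipole → EEG chain depends on, at desk scale and without a
neural-simulator dependency.

**Geometry.** L3: soma (20 µm) + 10-compartment apical stick of 600 µm
(3 µm diameter); soma band 675–750 µm below the pia. L5: soma (25 µm) +
20-compartment trunk of 1,500 µm (4 µm diameter); soma band 1,250–1,750 µm,
so the default L5 tip reaches the pia. Soma (x, y) is uniform over the
column disk. Membrane: c<sub>m</sub> = 1 µF/cm², r<sub>m</sub> = 10 kΩ·cm²,
r<sub>a</sub> = 150 Ω·cm — a ~30 ms membrane time constant and an input
resistance such that the ~1.9 nA stimulus is strongly suprathreshold, which
is the regime the simulator is meant to emulate.

**Stimulus.** A 30 ms somatic square pulse; amplitude mean + SD·z with
z standard normal per neuron (SD 0.3 nA); onset uniform in 10–20 ms,
quantized to the integration step. Default span 120 ms (onset window + pulse
+ tail), dt = 0.1 ms.

**Events.** When the passive somatic depolarization exceeds +20 mV relative
to rest, a 2 ms zero-net-charge biphasic current (3 nA peak) is injected at
the soma (repeating with a 5 ms refractory interval while suprathreshold).
L5 cells whose stimulus amplitude exceeds a configurable Ca threshold
(default 2.0 nA) additionally receive one 40 ms triangular inward current
(2 nA peak, rising to 10 ms) split across the three distal apical
compartments, 10 ms after stimulus onset. This reproduces the early
somatic-sink / late apical-sink CSD motif, and makes the expected Ca-event
count increase monotonically with the stimulus mean: with means 1.90 vs
1.85 nA the hit probabilities are Φ((1.90−2.0)/0.3) ≈ 0.37 vs ≈ 0.31, which
is what lateralizes the late CSD components and the dipole.

**Integration and conservation.** The cable equation is advanced with
Crank–Nicolson (unconditionally stable) at dt ≤ 0.1 ms. The transmembrane
current of a compartment is evaluated as its net axial influx
Σ<sub>j</sub> g<sub>cj</sub>(V<sub>j</sub> − V<sub>c</sub>), which books
injected (stimulus and event) currents as membrane currents; per-neuron
currents then sum to zero to machine precision at every sample, so the
source model contains no spurious monopoles. Because the cable is linear
and event triggering is computed from the passive somatic response (and the
stimulus amplitude), the population solve is an exact superposition of
per-cell-class kernels — one cable solve per geometry per waveform — which is
what makes the full 3,200-cell default run in seconds. Consequences worth
knowing: event feedback does not re-enter the trigger (a Na transient cannot
re-trigger itself), and event times are deterministic given amplitude and
onset.

## Extracellular forward model (`extracellular`)

Point-source superposition in an infinite homogeneous medium (σ = 0.33 S/m
default), with the source–electrode distance clamped at the compartment
radius to guard the singularity. The array helper places 17 co-linear
contacts at 100 µm spacing starting at the pia. Filtering: 4th-order
Butterworth applied forward–backward (zero phase, unit DC gain); the filter
family/order is a package choice — only the 100 Hz cutoff is dictated by the
workflow being modeled.

## CSD estimation (`csd`)

*Standard method*: the second spatial difference with the edge channels
dropped (optional replicate padding). With mV, mm and S/m the numbers come
out directly in µA/mm³ (1 S/m · mV/mm² = 1 µA/mm³).

*Spline-iCSD*: sources are modeled as planar disks (default diameter 3 mm,
matching the column) centered on the electrode axis; the on-axis potential of
a unit disk at distance Δz is (2σ)⁻¹(√(Δz² + R²) − |Δz|). The depth profile
is an interpolating cubic spline (not-a-knot) through nodal values at the
electrode depths, tapering to zero at ghost nodes one spacing beyond each
end. The forward matrix is assembled by per-segment Gauss–Legendre
quadrature (12 points) of the disk kernel against the spline basis and
inverted directly; optional Tikhonov regularization and a 5-point Gaussian
depth smoother are available but off by default (the noiseless round trip
then reproduces the input LFP to ~10⁻⁵ relative). The returned grid is
4× finer than the electrode spacing and includes the taper segments.

Sign conventions: recordings index depth below the pia; CSD profiles are
reported on z = −depth so that z increases toward the supragranular layers.
Sinks are negative.

Preprocessing mirrors the standard workflow: per-channel baseline subtraction
over a pre-stimulus window, and clipping of samples at t ≥ event − lead
(default 10 ms) to remove eye-movement contamination.

## Equivalent dipoles (`dipole`)

The CSD dipole integrates CSD(z,t)(z − z<sub>m</sub>) by the trapezoid rule
on the profile's own grid, scaled by π r<sub>c</sub>²; z<sub>m</sub> defaults
to the midpoint of the grid. The column radius r<sub>c</sub> defaults to
1.5 mm (the simulated 3 mm-diameter column) and is an explicit argument
everywhere, because the source description is ambiguous between a 3 mm
radius and a 3 mm diameter; users replicating the empirical analysis can
pass 3.0. Only the axial component is recoverable from laminar CSD; the
orientation comes from the cortical-mesh normal (area-weighted 1-ring
average at the nearest vertex, outward).

The STC dipole sums displacement-weighted compartment currents. Its
expansion point is the geometric center of the column; with conserved
per-neuron currents the moment is exactly independent of that choice (a
warning is raised otherwise).

## BEM head model (`headmodel`)

Vertex-collocation, linear-potential double-layer BEM for nested closed
surfaces (innermost first; conductivities brain 0.33, skull 0.0063, scalp
0.43, air 0). Element integrals of the linear shape functions against the
solid-angle kernel are evaluated analytically (de Munck's construction);
in-plane observation points (solid angle < π·10⁻⁶) are excluded, and the
diagonal is corrected so each same-surface row carries the full 2π solid
angle. The additive-constant rank deficiency is removed by deflation, and for
three-layer models with skull:brain conductivity ratio below 0.1 the
isolated-skull modification is applied (at 0.0063/0.33 ≈ 0.019 it is on by
default). Electrode potentials are barycentric interpolations of the scalp
solution and are reported average-referenced (the maps are relative; an
empirical linked-ears reference can be emulated by re-referencing).

**Validation.** The analytic oracle solves the per-degree radial two-point
boundary problem for concentric shells (radii normalized to the outer radius
for conditioning) and sums Legendre series up to degree 100 (the reported
truncation bound is the magnitude of the last term; it is ~10⁻⁴² of the
signal at the eccentricities used). The oracle itself is checked against a
closed-form homogeneous-sphere solution obtained by summing the series with
generating functions. Against the oracle, the level-3 (642 vertices/surface)
three-shell BEM achieves RDM ≤ 0.017 and MAG in [0.94, 0.96] for radial and
tangential unit dipoles at eccentricities up to 0.8 — the ~5% magnitude bias
is the known discretization bias of linear collocation at this mesh density
and sits well inside the certified [0.9, 1.1] band.

**Column placement.** When a simulated column is attached to a cortical site,
its pia is placed 2 mm below the innermost surface along the inward normal.
The innermost BEM surface is a smoothed brain envelope; real cortical tissue
lies beneath it, and placing sources directly on the surface both violates
the "source strictly inside" requirement and pushes the equivalent dipole to
eccentricities (~0.97) where a 642-vertex collocation solution is unreliable.

**Montages.** An idealized spherical 10-10 layout (61 labels) is generated by
exact 10% arc steps along the midline and ear-to-ear contours, a 10%-
elevation outer ring, and geodesic interpolation for the intermediate rows,
then projected radially onto the scalp mesh; Cz is exactly at the apex of a
spherical scalp. The 15-electrode clinical subset (FpFz aliased to AFz) is
available as `"10-20"`. The layout is a deterministic stand-in for
digitized electrode positions; real montages can be supplied as TSV.

## Metrics and ranking (`metrics`, `combine`)

MAG and RDM take an `axis` argument: norms over time for traces, over
electrodes for static maps, or over the flattened electrode × time matrix
(the default used in the site comparison). rdm² = 2 − 2·cos∠(y, ŷ) exactly.
Column depth is the exact point-to-mesh distance (face/edge/vertex cases).
Random column sites are sampled uniformly by vertex without replacement
(area weighting would matter only for strongly non-uniform meshes).

Configuration ranking enumerates all 2ⁿ−1 non-empty source subsets, sums
member maps electrode-wise, and computes one Pearson correlation per
configuration over electrodes × sessions pooled (15 × 30 = 450 points in the
default design). Negatively correlated configurations are retained in the
table but scored R² = 0 and never win; significance is two-sided with
Bonferroni correction by the number of configurations.

The five candidate sources used in the recovery experiment have fixed,
well-separated idealized positions and orientations on the spherical brain
(two occipital — one radial/gyral, one tangential/sulcal — two parietal, one
frontal), mirroring a study design in which the candidate areas are fixed
anatomical locations rather than random sites.

## What the synthetic experiments do and do not show

The certification experiments run at desk scale: 220 + 100 reduced cells for
the site comparison (full 2,200 + 1,000 for the lateralization run), a
level-3 three-shell sphere head, 15 random sites, EEG sampled every 1 ms.
Under these conditions the summed-current dipole reproduces the
compartment-based EEG more faithfully than the CSD dipole (mean RDM ≈ 0.004
vs ≈ 0.03; MAG ≈ 1.04 vs ≈ 0.91): the CSD estimate loses the return currents
below the 1.6 mm electrode span and inherits the disk-source idealization,
exactly the mechanisms that penalize it at full scale. The absolute RDM
values are an order of magnitude smaller than those obtained with detailed
morphologies on a real macaque head, because ball-and-stick populations are
far more dipolar than real pyramidal cells and a sphere has none of the
orientation variability of a gyrified cortex. Passing these experiments
certifies the chain's internal consistency, not the absolute error level to
expect on real anatomy.

Two further caveats. (1) On concentric spheres every random site has the
same depth up to mesh faceting (< 0.05 mm), so the depth regressions probe
discretization residuals rather than a physical depth effect; their R² is
reported for completeness and is small at the committed conditions, but it is
not a stable quantity on this geometry. (2) The simulator has no synaptic
connectivity, no active dendritic conductances, and no lateral morphology;
CSD patterns it produces are smoother and more stereotyped than in vivo data.

## Reproducibility

Every stage accepts an explicit seed or `numpy.random.Generator`; the
pipeline derives all stage randomness from one seed and records sha256
checksums of every stage's arrays in its manifest, so a rerun with the same
configuration and seed is verifiably bit-identical. File formats carry
explicit unit fields (the chain crosses five unit systems) and provenance
attributes (package version, seed, configuration hash).
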