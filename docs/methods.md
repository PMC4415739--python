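# Methods

## Physical model

The device is a closed 100 × 100 µm microfluidic chamber (origin at the
centre) holding one spherical cell, modelled as a 20 µm diameter disc at
the centre, suspended in PBS between a pair of gold electrodes with an
8 µm gap. At the operating frequencies (kHz) the magnetic field is
negligible and the drive is time-harmonic, so the complex phasor
potential obeys the electro-quasistatic equation

    ∇·(κ ∇φ) = 0,    κ(x) = σ(x) + j ω ε₀ εᵣ(x),

piecewise-constant κ per region. Gold is ~10 orders of magnitude more
conductive than anything else in the chamber, so electrodes are treated
as perfect conductors: Dirichlet surfaces (φ = V on the driven
electrode, φ = 0 on the grounded one), never meshed as material. The
chamber walls are insulating (homogeneous Neumann); a grounded-wall
alternative can be emulated by adding wall electrodes, but a closed
PDMS/glass chamber is electrically insulating, which fixes the default.

Because the cell (20 µm) is wider than the gap (8 µm), every electrode
family's faces overlap the cell footprint; metal displaces cytoplasm
(electrode label wins), so all families contact the cell directly.

### Materials

* PBS: σ = 2×10⁻⁶ S/m, εᵣ = 136, frequency-independent. This
  conductivity is the literature value adopted for this device model;
  it is ~6 orders below a physiological saline (~1.6 S/m), which makes
  the buffer displacement-dominated above a few kHz. It is deliberately
  not "corrected": the impedance scales and sensitivities modelled here
  depend on it. Users can substitute their own `MediumProperties`.
* Cell: empirical σ(f, V) and εᵣ(f, V) tables on the 5–100 kHz ×
  0.1–1.0 V grid, packaged as CSV (`src/cellimp/data/`). The voltage
  dependence is an empirical stand-in for field-induced membrane
  effects (ion-channel opening raises the apparent conductivity); the
  PDE itself stays linear at each (f, V) operating point. No
  mechanistic dispersion model (Cole–Cole, Schwan) is layered on top —
  the tables *are* the material model.
* Lookup: exact at grid nodes, bilinear in (f, V) between them. Below
  5 kHz the electrode double layer makes the tabulated values
  physically untrustworthy, so the default policy refuses
  out-of-range lookups; an explicit `extrapolate` policy extends in
  frequency (log–log for σ, i.e. a local power law; log-linear for εᵣ)
  and a `clamp` policy pins to the grid edge. Validation reports — but
  never silently repairs — violations of the monotone trends (σ
  non-decreasing in f and in V) that the packaged tables satisfy
  throughout.

### Electrode families and their dimensions

Only the 8 µm gap, the chamber size and the cell size are stated device
dimensions; the remaining electrode dimensions are parametric with the
following defaults (all configurable per layout):

| family   | default geometry |
|----------|------------------|
| standard | rectangular finger from the chamber edge, tip width 6 µm |
| cross    | plus-shaped electrode: 4 µm wide, 20 µm long arm pointing at the cell, perpendicular 4 × 20 µm crossbar at the arm midpoint |
| circle   | finger ending in a circular-arc face (radius 10 µm) concave toward the cell, cup span 12 µm, on-axis face separation = gap |
| parallel | 18 × 10 µm bars above and below the cell (drive axis y); bar length slightly under the cell chord at the bar face, so the whole inner face contacts the cell |

These defaults were *derived*, not copied: the only published
constraints on the shapes are qualitative — the wide-contact families
(circle, parallel) must show higher field strength, lower impedance
magnitude and higher sensitivity than the narrow-tip families (cross,
standard), with circle ≈ 2× cross intracellular field. A literal
reading in which the crossbar sits at the cross tip and all tips are
10 µm wide produces the *opposite* orderings in this solver (the
crossbar gives the cross electrode the largest cell contact and hence
the strongest intracellular field), so the defaults above were selected
as the simplest reading of each shape description that reproduces the
qualitative orderings across the full sweep. The binary orderings were
the only selection criterion; all printed magnitudes are then measured,
not fitted. This is the largest modelling uncertainty in the package.

For the circle family the cup corners necessarily approach closer than
the on-axis faces (an arc of radius ≈ cell radius cannot cup the cell
otherwise), so its `gap` parameter means the on-axis face separation;
`electrode_gap_distance` always reports the true minimum distance
(4 µm for the default cup).

## Discretisation

* Mesh: structured triangulation (alternating diagonals, which keeps
  the mesh exactly mirror-symmetric), node coordinates exact multiples
  of the step so feature edges land on grid lines. Nodes within half a
  cell of a curved material boundary (cell circle, arc faces, annulus
  electrodes) are radially snapped onto it, restoring O(h²) geometric
  accuracy; snaps that would degenerate a triangle (area < 0.05 h²)
  are reverted. Element regions are assigned by centroid
  classification; electrode-interior elements are excluded from
  assembly; electrode-region nodes carry the Dirichlet values.
* Elements: P1 triangles. The electric field is element-wise constant,
  E = −∇φ, |E| = √(|Eₓ|² + |E_y|²); no gradient recovery or smoothing
  is applied, and reported field statistics inherit the element-level
  granularity.
* Solver: complex sparse LU (SuperLU). No iterative tolerances, fully
  deterministic, bit-reproducible outputs.
* Terminal current: weak-form residual summed over the driven
  electrode's nodes (superconvergent flux extraction); charge balance
  between the two electrodes holds to ~1e−13 relative.
* Resolutions: 1 µm for full sweeps (~10⁴ nodes/solve, 484 solves in
  under a minute), 0.5 µm for production single-point numbers
  (~4×10⁴ nodes), convergence-checked against 0.25 µm. The annulus
  closed form verifies first-order-in-energy/second-order-in-potential
  behaviour (error contracts ≥3× per halving).

## Impedance, depth and sensitivity

A 2D solve yields current per unit depth; ohms require an out-of-plane
depth. `fem_impedance` defaults to 1 m (pure per-unit-depth numbers);
the study pipeline defaults to a 20 µm chamber depth — equal to the
cell diameter, i.e. the shallowest chamber that admits the cell, which
is the natural effective depth for a cross-section model of a
single-cell trap. Sensitivity and field ratios are depth-independent.

"Without-cell" (solution-only) references replace the cell disc with
PBS on the identical mesh. Since the PDE is linear per operating point,
|Z_solution| is exactly voltage-independent and is solved once per
(shape, frequency).

The equivalent circuit holds the only electrode-interface physics: the
double-layer capacitance C_d exists in the circuit model and nowhere in
the FEM (consistent with restricting the FEM to ≥5 kHz). Circuit
fitting minimises stacked log₁₀-magnitude and normalised-phase
residuals over log-parameters, from a fixed 27-point initialisation
grid (deterministic multi-start, Levenberg–Marquardt); elements whose
corner frequencies fall outside the fitted band are weakly
identifiable, so the fitting fixtures span 10²–10⁸ Hz.

## Field statistics

Line profiles sample the element-constant |E| along an axis-parallel
line through the cell centre (≥200 samples across the cell; samples in
metal are masked). The extrema report takes intracellular statistics
over cell elements and extracellular statistics over PBS elements
within a 5 µm shell around the cell boundary. An optional band
restriction around the drive axis exists but is off by default: for
families whose metal lies on the drive axis the banded extracellular
set is empty, because the electrodes displace exactly that PBS.

## Synthetic fixtures

The fixture generator makes every stage testable without the packaged
tables: a plate device (exact linear potential; the P1 solution is
nodally exact, so solver errors surface as >1e−10 deviations), a
concentric annulus (logarithmic potential and closed-form terminal
current, used for convergence-order checks), a null-contrast cell
(cell κ = PBS κ; sensitivity must vanish), and synthetic material
tables from the monotone law σ = σ₀ (f/f₀)ᵃ e^{bV}, εᵣ = ε₀, which pass
validation by construction and give interpolation a known ground truth.
Spectra synthesised from a known circuit, optionally with seeded
multiplicative noise (the package's only random element), close the
loop on the fitter. These fixtures exercise solver, extraction and
pipeline mechanics; they do not emulate biological variability, 3D
current spreading, electrode polarisation or measurement noise, so
passing them validates the numerics, not the fidelity of the 2D model
to a physical device.

## Known limitations

* 2D cross-section: out-of-plane spreading is absorbed into a single
  depth factor; absolute ohm values are order-of-magnitude estimates.
* With an 8 µm gap and Dirichlet electrode faces inside a 20 µm cell,
  the on-axis intracellular field is pinned near V/gap (≈1.25×10⁵ V/m
  at 1 V) for every family; models that place most of the voltage drop
  elsewhere (e.g. in a double layer) would report lower intracellular
  fields. The quasistatic model cannot reproduce such readings.
* Electrode dimensions beyond the gap are inferred (see above);
  absolute per-shape numbers shift with those defaults, while the
  cross-family orderings are robust across the readings explored.
* No adaptive meshing, higher-order elements, time-domain solves, 3D,
  or constant-phase-element/Warburg circuit extensions.
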