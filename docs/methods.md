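# Methods

`epidermsim` is a center-based (off-lattice) stochastic simulator of epidermal
homeostasis: keratinocytes are generated by anchored stem cells on a rigid
basement membrane, migrate and differentiate as they are pushed away from it,
flatten into corneocytes that stack into a stratum-corneum sheet, and are shed
from the free surface. The package exists to ask a geometric question: which
basement-membrane undulation patterns (sinusoidal bumps of given amplitude and
wavelength, or textile-like fiber grids of given fiber thickness and spacing)
support a thick, stable epidermis, compared with a flat membrane.

## Model

### Cells and states

Each cell is an axisymmetric ellipsoid with semi-axes (a, a, c) and intrinsic
radius r0 = 5 µm (a = c = r0 for all living cells). The lifecycle is a strict
five-state chain:

    STEM  --(division)-->  PROLIF -> SPINOUS -> GRANULAR -> CORNEOCYTE -> shed

* **STEM** cells sit on the membrane, pinned by a harmonic spring to an
  on-surface anchor; they never transition and never die, so the stem count is
  invariant over a run. Division is a memoryless (exponential) clock with mean
  `division_period_h` (default 12 h), *suppressed entirely* while more than
  `crowding_cap` cell centres lie within one cell diameter (2·r0) of the stem
  — contact inhibition. Daughters start as PROLIF at `daughter_offset_um`
  (7.5 µm — close enough to overlap the mother slightly, far enough that the
  birth force transient stays within the integrator's displacement guard) in
  a uniformly random upward-hemisphere direction, seated at the
  membrane-spring equilibrium clearance if a steep flank would put them
  below the surface.
* **PROLIF → SPINOUS** is positional: it fires deterministically once the
  cell's vertical clearance above the membrane exceeds `diff_height_um`
  (12 µm ≈ one cell diameter), standing in for loss of membrane contact.
* **SPINOUS → GRANULAR** and **GRANULAR → CORNEOCYTE** are exponential clocks
  with means `spinous_dur_h` = `granular_dur_h` = 24 h. Because exits are
  memoryless, the stationary spinous occupancy under constant influx has the
  M/M/∞ closed form (influx × mean residence), which the tests exploit.
* **CORNEOCYTE**s are dead and mechanically passive. Their aspect ratio
  q = c/a relaxes exponentially toward `target_aspect` (0.2) with time
  constant `flatten_tau_h` (6 h); the semi-axes are rescaled every step so
  a²c = r0³ holds exactly (volume conservation is enforced algebraically, not
  numerically). Desquamation is an exponential clock with mean
  `desquam_dur_h` (64 h, calibrated so shedding balances crowding-gated
  production at the desk-scale flat steady state) that runs **only while the cell is exposed at the
  free surface**: a corneocyte is blocked whenever any other cell centre lies
  inside a 45° upward cone of height 3·r0 above it. Interior corneocytes are
  therefore never removed and the stratum corneum is shed coherently from the
  top.

An optional scalar calcium proxy (`calcium: on`) relaxes toward a
height-dependent target (0 at the membrane, 1 above the granular band) with a
1 h time constant and multiplies the SPINOUS→GRANULAR rate. It is a stand-in
for full intracellular calcium dynamics, is off by default, and when off the
trajectory is bit-identical to a run without the feature.

### Mechanics

Overdamped Euler–Maruyama: Δx = (ΣF/γ)·dt + η·√dt·ξ, with γ = 1 (drag
normalises force units), dt = 0.02 h, and thermal noise η = 0.2 µm·h^(-1/2)
applied only to PROLIF/SPINOUS/GRANULAR cells (stems are anchored,
corneocytes passive). Forces:

* **Cell–cell contact.** For centre separation d along unit vector û, the
  contact distance is R = r_i(û) + r_j(û) with the direction-dependent
  ellipsoid radius r(û) = a·c/√(c²sin²θ + a²cos²θ) (θ measured from the
  vertical). Repulsion k_rep·(R−d) inside contact; adhesion ramping linearly
  from k_adh at contact to zero at R + adh_range (k_rep = 10, k_adh = 1,
  adh_range = 2 µm). The anisotropic radius lets flattened corneocytes
  overlap-test laterally at ~2a but stack vertically at ~2c, which is what
  makes the corneocyte raft form without an ellipsoid–ellipsoid contact
  solver. Coincident centres get a deterministic hash-seeded push-apart.
* **Membrane contact.** The membrane is a rigid height field h(x, y), periodic
  in x and y. Penetration is measured as the *perpendicular clearance*
  (vertical gap × n_z, identical to the vertical gap on a flat membrane):
  engagement when it is below the vertical semi-axis c, force
  k_mem·(c − clearance) along the outward normal (k_mem = 20). Measuring
  penetration vertically instead is wrong on near-vertical fiber flanks,
  where it overestimates penetration by the flank slope and produces forces
  large enough to destabilise any explicit integrator.
* **Anchoring.** Stems feel a spring k_anchor = 20 toward their on-surface
  anchor point.

Neighbour search is a uniform spatial hash (counting sort) over periodic
(x, y) and binned z, with the bin edge set by the largest current interaction
range; grid sums are verified against a brute-force all-pairs oracle to
1e-10. A runtime guard aborts with the offending cell id if any single-step
displacement exceeds 0.5·r0; before the guard trips, transient force
pile-ups are resolved by adaptive substepping of the deterministic part of
the motion (forces recomputed over up to 8 subdivisions; no extra random
draws, so the random stream is unchanged). Each run starts with a short
deterministic equilibration of the seeded stems (clamped relaxation steps,
no clocks, time does not advance) so seeding overlaps do not contaminate
the first stochastic steps. All random draws flow through one PCG64
generator in a fixed per-step order (cells in id order), so a run is bitwise
reproducible from (config, seed).

### Membrane geometries

* flat: h ≡ 0.
* sinusoidal bumps (default): h = (A/2)·sin(2πx/λ)·sin(2πy/λ), so
  `amplitude_um` is the peak-to-trough excursion; an isotropic 2D undulation
  resembling dermal papillae. A 1D groove variant (`profile: grooves`) is
  available for sensitivity studies. The domain must hold a whole number of
  wavelengths (within 1%): an odd number of half-wavelengths would leave a
  mirror kink in the surface normal at the periodic seam, which traps cells
  in a force discontinuity.
* fiber grid: two orthogonal arrays of half-embedded cylinders (axis in the
  base plane, crown rising one fiber thickness above z = 0) spaced
  thickness + interval apart — an idealisation of a woven textile that keeps
  exactly the two parameters the substrate table provides. The height field
  is the upper envelope and is continuous; weave over/under structure is
  deliberately ignored. The packaged preset table lists ten polyester
  textiles plus the measured human papillary geometry (ridge height 51 µm,
  interval 105 µm).

Normals come from the analytic gradient for flat/sinusoidal surfaces and
central differences (step 1e-3 µm) for fiber grids.

## Why the crowding cap is 4

Contact inhibition is the only production throttle in the model, and removal
at the free surface is capacity-limited (only the exposed top layer of
corneocytes can be shed), so homeostasis requires that the cap actually
engage at basal close packing. The cap counts centres within one cell
diameter of the stem; a membrane-seated stem has its lower half-space empty,
which caps that count at roughly 6–8 even at dense packing. Measured stem
neighbourhood counts in crowded flat-membrane runs span 4–8 (median 6). With
a cap of 12 division never throttles and the tissue grows without bound
(~9.4 births/h against ~1 removal/h on the default domain); with a cap of 4
the 500 h flat run plateaus — the 5-seed 95% CI of the total-count slope over
the final quarter of the run straddles zero — while retaining a substantial
multi-layer stratum corneum. The cap is therefore 4 by default and, like
every lifecycle constant, configurable.

## Why undulation thickens the tissue

Stems are seeded at fixed *lateral* spacing (jittered hexagonal lattice,
10 µm), so an undulated membrane carries the same number of stems spread over
a larger 3D surface. Their neighbourhoods are emptier, contact inhibition
engages less often, and basal output per unit of plan area rises with surface
slope — which grows with amplitude and shrinks with wavelength (∝ A/λ). The
troughs additionally hold extra living-layer volume below the mean surface.
Both headline observations — thicker stratum corneum and living layer on an
undulated membrane, and the large-amplitude/short-wavelength regime — emerge
from this geometry; they are not imposed anywhere.

## Readouts

* `count_layers`: corneocytes vs everything else (the living layer) — the
  standard two-colour partition of a stained section.
* `section_areas`: cells intersecting a 10 µm-thick virtual slab are drawn as
  their (x, z) ellipse cross-sections on a pixel grid (default 0.25 µm);
  pixels at or below the membrane profile are masked out, mirroring the
  removal of fiber cross-sections from section images before quantification;
  corneocytes win raster ties (compacted SC overlies living tissue in
  stained sections). Areas are reported in µm² per 100 µm of section length.
  Rasterisation error is ~2% at the default pixel size for thin corneocyte
  ellipses and <1% at 0.1 µm.
* `thickness_profiles`: per lateral bin (default: one bin per cell
  diameter, ~10 µm, of lateral extent), living thickness =
  highest living-cell top minus membrane height, SC thickness = highest
  corneocyte top minus the living top (floored at 0); interface roughness is
  the standard deviation of the interface height over bins.
* `render_section`: cross-section raster with membrane green, living cells
  purple, cornified cells red.
* `compare_conditions`: one-way ANOVA plus Tukey HSD (α = 0.05) over
  replicate metric tables, via scipy/statsmodels.

## Experiments and problem sizes

All drivers use a paired-seed design: each replicate seed is reused across
conditions so condition contrasts are within-seed. Defaults run on a
desk-scale 100×100 µm domain (1/9 the area of the 300×300 µm reference
region; `full_roi=True` restores the full region) for 500 simulated hours
(> 40 stem division periods, several stratum-corneum turnovers), snapshot
every 25 h. These sizes are the package's chosen study conditions; every
driver accepts overrides.

* flat vs sinusoidal: amplitude 50 µm / wavelength 100 µm (the measured
  papillary geometry, rounded) against flat, 5 paired replicates; reports
  per-replicate SC and living counts and the paired ordering.
* amplitude/wavelength sweep: A ∈ {10, 30, 50} µm × λ ∈ {60, 100, 200} µm;
  each condition's domain is the whole multiple of λ nearest 100 µm (120,
  100, 200 respectively). Tissue output per unit area carries a finite-size
  effect of the periodic domain (larger domains sustain more interface
  heterogeneity, hence more open basal sites and higher per-area output), so
  every condition is scored as *excess* thickness over a flat control run on
  the same domain with the same seed. The report carries Spearman rank
  correlations of excess living thickness and excess stratum-corneum
  thickness with A and with λ. In this reconstruction the stratum-corneum
  regime is the robust one (strongly positive in A, negative in λ); the
  living-layer wavelength effect is weak and hump-shaped, peaking near the
  papillary ~100 µm wavelength — very short wavelengths carve troughs
  narrower than a cell, which the tissue bridges over.
* textile panel: fiber-grid presets plus a flat control, Tukey HSD against
  the control and a thickness ranking. The ranking is reported, not asserted:
  the mechanical parameters are reconstructions, so the in-vitro ranking is
  not presumed.

## Synthetic data and what tests show

The package needs no external data; test inputs are built by `make_fixture`
(hand-specified two-layer slabs, a single stem, seeded random clouds) and by
the simulator itself. The generator emulates geometry and state structure
only — it does not emulate biochemical signalling, cell-shape remodelling
beyond axisymmetric flattening, substrate deformation, or any wet-lab
measurement. Passing tests therefore demonstrate internal consistency of the
model and reproduction of the *qualitative* undulation effects, not
quantitative agreement with cultured epidermal equivalents.

## Numerical choices and degenerate inputs

* dt = 0.02 h against stiffness 10–20 and γ = 1: relaxation ratios ≤ 0.4,
  with the 0.5·r0 displacement guard as a hard backstop.
* Exponential-clock probabilities use expm1 for small-dt accuracy.
* Flattening rescales semi-axes from the aspect ratio in closed form, so
  volume drift is at rounding level regardless of step count.
* Coincident cell centres: deterministic hash-seeded separation, never NaN.
* Empty lateral bins in thickness profiles contribute zero thickness; an
  empty snapshot renders as membrane only; zero-amplitude sinusoids are
  exactly flat membranes.
* Snapshots are checked for NaN/Inf and for the exact N = N0 + births −
  removals identity every time they are taken.

## Known limitations

* The lifecycle and force constants are conventional center-based-model
  choices, not fitted to measurements; only qualitative orderings should be
  read from the outputs.
* Removal capacity is set by the exposed-surface geometry, so the
  steady-state stratum-corneum size is sensitive to the desquamation
  lifetime and the exposure cone.
* Suprabasal cells never divide; there is no transit-amplifying compartment,
  apoptosis, or lineage competition.
* The membrane is rigid: no substrate deformation feedback, and textile
  weave structure is reduced to a crossed-cylinder grid.
* Periodic lateral boundaries on a ~100 µm domain suppress long-wavelength
  tissue modes; the full-region option mitigates but does not remove this.
* Homeostasis is demonstrated at the desk-scale domain. Larger periodic
  domains sustain more interface heterogeneity, which admits more divisions
  per unit area; a 200 µm flat domain still grows slowly at 500 h. Contrasts
  between conditions are therefore always evaluated against controls on the
  same domain.
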