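# Methods

`frustulight` models how the silica cell wall (frustule) of the small
biraphid pennate diatom *Gomphonema parvulum* modulates light in the near
field. The valve is treated as a set of integrated optical components — a
thin slab (the valve face), curved fibre-like mantle edges, grid-like
costae/areolae elements, lens-like thickenings (nodule, sternum), raphe
slits, girdle bands — whose 2D cross-sections are simulated one at a time
and compared against closed-form optics.

## Geometry model

All cross-sections (CSs) are built parametrically from the weighted-mean
structural parameters of the valve (`ValveParameters`): face thickness
D_v = 0.17 µm, striae spacing d_str = 0.49–0.57 µm, areolae spacing
d_a = 0.214 µm, mantle height/width 0.58/0.184 µm, sternum 0.26 µm ×
0.64 µm, nodule 0.38 µm × 0.86 µm offset 0.18 µm along the apical axis,
raphe slits 0.023 µm separated 0.54 µm, girdle bands 0.184 × 2.84 µm spaced
0.01 µm. The coordinate convention is x = propagation axis (µm), y =
transverse; the external valve face sits at x = 4 µm by default and
wavelengths are always quoted in nm.

Design choices made where the source data leave the geometry open:

* **Mantle profile.** The mantle is a circular arc sweep of the slab
  mid-plane, turning θ_M = 70° from the face plane, with radius set so the
  rim elevation along x equals h_M; the strip width is W_M,CS (0.184 µm for
  the central longitudinal CS, up to 0.334 µm for rim-near slices). The
  profile is parameterized so alternative rim shapes can be swapped in.
* **Grid fill factor.** The costae grid's fill factor is not measured
  directly; the default ff = 1 − (internal areola diameter)/d_str ≈ 0.70
  takes the areola aperture as the groove width. Configurable.
* **Grid unit counts.** 11 units for the d = 0.50 µm grid CS and 9 for the
  d = 0.565 µm one (≈13 visible striae minus the sternum interruption);
  configurable.
* **Grid units** are plano-convex: flat side at the external face, circular
  cap of 0.07 µm sag on the internal side (the costa profile). The
  shortened-stria defect variant displaces one unit by the gap width so it
  merges with its neighbour — same silica area, one closed gap.
* **Edge smoothing.** All convex silica corners carry circular fillets of
  radius 0.02 µm (the smallest feature scale the reconstruction resolves);
  filleting changes CS areas by < 2 %, verified in the tests.
* **Hypovalve scale.** The hypovalve is "slightly smaller" than the
  epivalve; the frustule assembly mirrors the epivalve and scales it by
  0.97 about its centroid, with four girdle bands (two per side, stepped one
  band width inward, spaced d_girdle along x) bridging the valves.
* **Pore occlusions** are off by default (no significant effect on the
  near-field pattern).

Rasterization converts a scene to n(x, y) on a regular grid: cell centres
are classified by point-in-polygon tests, cells near boundaries (including
features thinner than a cell, e.g. the 23 nm raphe slit) are supersampled
8×8 and carry the permittivity-averaged index n = √(f·n_v² + (1−f)·n_m²).
The raster reproduces polygon areas to well under 1 %.

## Wave solver

The solver is a 2D scalar finite-difference frequency-domain (FDFD)
discretization of ∇²E + k₀²n²E = 0 for the out-of-plane (TE) electric
field. For TE polarization and piecewise-constant media this scalar
equation *is* the 2D Maxwell problem, so the solver fills the same role as
a frequency-domain finite-element wave-optics run. Choices:

* **Polarization.** TE (out-of-plane E) throughout; TM is out of scope.
  GMR positions are polarization dependent, which bounds the fidelity of
  comparisons with vector-FEM reference values (see Limitations).
* **PML.** Stretched-coordinate perfectly matched layers on all four
  sides: s(u) = 1 + iσ(u)/k₀ with a cubic σ profile graded for a nominal
  round-trip reflection of 1e-8; default thickness 1.5 λ/n_m. Measured
  spurious reflection in a homogeneous run is < 1e-4 of the incident
  amplitude.
* **Dispersion-corrected mass term.** k₀²n² is replaced by
  (2/h²)(1 − cos(k₀nh)), which makes axis-aligned plane waves exact on the
  grid at any index; oblique propagation retains the stencil's anisotropy
  error (~(k₀h)²/24).
* **Source.** A total-field/scattered-field interface near the input
  boundary injects the incident wave with E_input = 1 V/m; the total-field
  region ends at the right PML edge, where the same identity annihilates
  the incident wave exactly. With the default full-width source and Neumann
  (zero-flux) transverse walls, a homogeneous medium reproduces
  E_Norm = 1 V/m to machine precision; a finite-width source (e.g. the
  80 µm source in the 100 µm full-scale box) uses a raised-cosine taper
  over the outer 10 % of its width.
* **Linear algebra.** One sparse LU factorization (SuperLU) per
  wavelength; bit-reproducible, relative residual checked against 1e-8. A
  memory guard refuses problems beyond 4·10⁶ unknowns with a suggestion to
  coarsen.
* **Resolution.** h = λ/(res_factor·n_v); res_factor = 15 for tests and
  desk-scale acceptance runs, 20 for production. Validation: slab
  reflectance/transmittance match the transfer matrix within 2 % of the
  incident intensity across 300–800 nm in air and water at res_factor 15.
* **Domains.** The full-scale 40 × 100 µm box is supported; tests and the
  acceptance runs use reduced domains (20 × 12 µm for focusing sweeps,
  8–10 µm long boxes for grating/GMR work whose observables live within a
  few µm of the structure). Problem sizes range from ~5·10⁴ to ~1.5·10⁶
  unknowns.

## Closed-form predictors

* Single-slab (Airy/transfer-matrix) R and T at normal incidence, with
  R + T = 1 exactly for lossless slabs.
* Thin-film extrema: constructive reflection at λ = 2·n_sl·D_sl/(m + ½)
  (the π phase shift of the thin-to-thick reflection included), destructive
  at λ = 2·n_sl·D_sl/m; positions independent of the medium.
* Talbot length Z_T = (λ/n_m)/(1 − √(1 − (λ/(n_m d))²)) for small-period
  gratings, valid while the ±1 orders propagate (λ < n_m·d); the printed
  form of this relation is typeset ambiguously in the source literature and
  this reading is fixed by its paraxial limit 2d²n_m/λ.
* Grating orders: m propagates iff |m|·λ < n_m·d (strict).
* Waveguide cutoffs from the mode-count ratio 2·W·n_core/λ: mode m ≥ 1 cut
  off at λ = 2·W·n_core/m (537 nm for the 0.184 µm mantle, 975 nm for the
  0.334 µm one); the fundamental is always guided. The exact symmetric-slab
  TE cutoff (2·W·√(n_core²−n_clad²)/m) is provided as a clearly separate
  alternative.

## Observable extraction

* **R/T of slab-like CSs.** Upstream, the reflected amplitude is the
  standing-wave envelope half-excursion (env_max − env_min)/2 on an axial
  cutline, recovered robustly by complex least-squares demodulation against
  the two counter-propagating waves (window ≥ 2.5 spatial periods λ/(2n_m),
  ending 1 µm before the face). Downstream, the transmitted amplitude is the
  mean E_Norm on a transverse segment 0.5 µm behind the slab, clipped away
  from edge-fringe lobes. Both are squared to intensities.
* **Focusing spots** are connected components of E_Norm ≥ 1.1·E_input
  beyond the exit face; each carries peak strength E_Norm,f, the axial gap
  Z_f, and the axial FWHM L_f at the half level midway between peak and
  E_input (a spot-boundary definition stable under resolution changes).
  Sweeps track one spot by centroid continuity.
* **Photonic jets** are the brightest downstream component contiguous with
  the structure's shadow axis; waist = transverse FWHM at the peak, axis
  angle measured from the incident axis.
* **Talbot planes** are local maxima of the correlation between the
  transverse E_Norm profile (outermost grating unit dropped on each side)
  and a grating-registered cosine of period d; the registered (unshifted)
  template selects the integer self-image planes and rejects the
  d/2-shifted half-planes. Z_T is the mean plane spacing; the uncertainty
  is the spacing standard deviation floored at one grid cell.
* **GMR** is located by a coarse sweep (10 nm, or 5 nm for the first mode)
  of the mean E_Norm inside the silica of the grid region, refined on a
  1 nm grid around the coarse maximum; E_Norm,GMR is the interior maximum
  at resonance. A run with no interior enhancement above 1.2·E_input
  reports "no resonance".

## Structural statistics

Per-valve measurement tables (X_av,i ± dX_av,i) are reduced by the
inverse-variance weighted mean with the internal error (ΣW)^(−1/2) and the
Birge-style external error √(Σw(X−X_w)²/((N−1)Σw)); the larger of the two
classifies the dominant variation (within- vs between-valve) and sets the
parameter's precision. The formulas themselves are not printed in the
source material; the standard inverse-variance definitions are the only
conventional reading consistent with the internal/external comparison
logic. The synthetic-table generator draws valve means around a true value
(between-valve SD) and per-image measurements around each valve mean
(within-valve SD), reducing them exactly as real image measurements would
be; recovery of the truth within 2·dX holds for ≥ 95 % of 1000 seeded
replicates at the tabulated precisions.

## What the synthetic data do and do not emulate

Fixtures cover homogeneous media, laterally uniform slabs, rectangular
analytic gratings, two-slit slabs and measurement tables, each carrying an
independently computed closed-form ground truth. They emulate the *study
conditions* — printed structural means, λ ∈ 300–800 nm, n_v = 1.46,
n_m ∈ {1.00, 1.33} — not real micrographs: there is no measurement noise
model beyond Gaussian within/between-valve scatter, no 3D pore lattice, no
spatially varying silica index, and no girdle-band fine structure. Passing
tests therefore demonstrate correctness of the optics pipeline under the
statistical valve model, not agreement with new experimental data.

## Numerical choices and degenerate inputs

Ties in spot ordering break toward smaller Z_f. Degenerate geometry limits
are honoured: zero mantle width gives the bare rectangle, a nodule of
face thickness gives a slab, zero girdle spacing makes bands contiguous
(allowed), a hypovalve scale ≥ 1 is refused. Rasterization refuses
resolutions coarser than λ_min/(15·n_v). Wavelength sweeps adapt the
raster per wavelength and are bit-reproducible; no stage uses randomness
except the synthetic measurement tables (seeded).

## Known limitations

* Scalar TE only. Guided-mode-resonance positions computed here sit ~3–4 %
  blue of the reference vector-FEM values (both for the valve CS and for
  the analytic grating), consistent with an engine/polarization-level
  difference; first-mode positions agree within a few nm. Trends (red
  shift with pitch and thickness, enhancement growth with unit count) are
  reproduced.
* 2D cross-sections cannot give 3D amplitudes; absolute field strengths of
  jets, Talbot fringes and resonances are mesh- and engine-dependent, so
  only positions, trends and orderings are treated as comparable.
* The mantle curvature, grid fill factor and hypovalve scale are modelling
  choices (documented above), not measured quantities.
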