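# frustulight

Near-field optics of the *Gomphonema parvulum* frustule — the nanopatterned
silica cell wall of a small biraphid pennate diatom — as a desk-scale,
fully scripted pipeline. The package is for biophotonics and
diatom-optics researchers who want to ask, without a commercial FEM
licence: how does a wavelength-scale porous silica valve reshape the light
field just behind it, and which of its structural components is
responsible?

The valve is decomposed into integrated optical components and each one is
modelled and simulated in 2D cross-section:

| component | optics it produces |
|---|---|
| valve face (thin slab, D_v = 0.17 µm) | thin-film interference, edge diffraction |
| curved mantle rim / girdle bands | fibre-like waveguiding |
| costae/areolae grids (d = 0.49–0.57 / 0.214 µm) | Talbot self-imaging, guided-mode resonance (GMR) |
| nodule and sternum thickenings | photonic jets, pattern splitting |

## The models

**Geometry.** Parametric 2D longitudinal/vertical cross-sections are built
from the statistical valve model (weighted-mean structural parameters),
assembled with shapely and rasterized to refractive-index grids n(x, y)
with sub-pixel permittivity averaging (n_v = 1.46 silica in air n_m = 1.00
or water n_m = 1.33).

**Solver.** A scalar TE finite-difference frequency-domain (FDFD) solver
for ∇²E + k₀²n²E = 0 with stretched-coordinate PML, a total-field/
scattered-field plane-wave source (E_input = 1 V/m) and one sparse LU
factorization per vacuum wavelength λ ∈ 300–800 nm. In 2D with TE
polarization this scalar equation is the exact Maxwell problem, so the
solver stands in for a frequency-domain FEM wave-optics run.

**Closed forms** used as ground truth: the single-slab transfer matrix;
thin-film extrema 2·n_sl·D_sl = m·λ and (m+½)·λ; the small-period Talbot
length Z_T = (λ/n_m)/(1 − √(1 − (λ/(n_m d))²)); grating orders
|m|·λ < n_m·d; waveguide cutoffs λ_c = 2·W·n_core/m.

**Observables** extracted from field maps: reflected/transmitted
intensities E²_Norm,R and E²_Norm,T, diffraction-driven focusing spots
(Z_f, L_f, E_Norm,f), photonic-jet metrics, Talbot length with
uncertainty, and GMR positions λ_GMR from coarse-then-fine wavelength
sweeps of the interior field.

**Statistics.** Per-valve measurement tables reduce to inverse-variance
weighted means with internal and external (Birge) errors, classifying
whether within- or between-valve variation dominates each structural
parameter.

## Worked example

Talbot self-imaging behind the analytic costae grating (pitch 0.5 µm,
fill factor 0.7, 11 units) at λ = 350 nm in air:

```python
from frustulight.geometry import build_analytic_component, rasterize
from frustulight.params import OpticalConstants
from frustulight.solver import SimulationConfig, solve
from frustulight.features import extract_talbot
from frustulight import theory

scene = build_analytic_component(
    "grid", {"d": 0.5, "ff": 0.7, "D": 0.17, "N": 11},
    OpticalConstants(n_v=1.46, n_m=1.00), face_x=2.0)
cfg = SimulationConfig(box_width_x=9.0, box_height_y=10.0,
                       source_width=None, res_factor=15.0)
grid = rasterize(scene, cfg.resolution_for(350.0, 1.46),
                 box=(0.0, -5.0, 9.0, 5.0), lam_min_nm=350.0)
fm = solve(grid, 350.0, cfg)
t = extract_talbot(fm, 0.5, scene=scene)
print(f"measured Z_T = {t.Z_T:.3f} ± {t.uncertainty:.3f} µm")
print(f"closed form  = {theory.talbot_length(350.0, 1.00, 0.5):.3f} µm")
print("planes:", ", ".join(f"{p:.2f}" for p in t.plane_positions), "µm")
```

prints

```
measured Z_T = 1.215 ± 0.016 µm
closed form  = 1.224 µm
planes: 2.41, 3.62, 4.83, 6.05 µm
```

i.e. the simulated grating self-images repeat every 1.22 µm along the
propagation axis, in agreement with the closed-form Talbot length, and the
four detected image planes sit 2.4–6.0 µm behind the input boundary.

The same machinery is scriptable from the shell:

```sh
$ frustulight theory extrema -d 0.17
{"constructive_reflection_nm": [331], "destructive_reflection_nm": [496]}
$ frustulight theory cutoff -w 0.184
537.3
$ frustulight theory orders --lam 550 --n-m 1.33 -d 0.5
[-1, 0, 1]
```

— the 170 nm valve face reflects most strongly near 331 nm and turns
transparent near 496 nm; the 184 nm mantle guides its first mode below
537 nm; in water the 0.5 µm grid still diffracts ±1 orders at 550 nm.

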