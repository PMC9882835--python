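# hyphoshell

Quantitative tools for fungal tip growth: **subresolution cell-wall
thickness mapping** from two-channel live-cell images, **thin-shell wall
mechanics** (Young's modulus, surface modulus, turgor), and a **feedback
model** of hyphal tip growth coupling exocytic-vesicle delivery, wall
assembly and turgor-driven expansion.

## Who this is for

Fungal cell biologists and biophysicists who image hyphae (e.g.
*Aspergillus*) with a membrane marker on the inner wall face and a lectin on
the outer face, and want local wall thickness `h` far below the diffraction
limit; and modelers studying how tip growth stays stable while the wall is
simultaneously deposited and stretched.

## The science in brief

**Thickness.** The two wall faces are labeled in different channels, so each
contributes one diffraction-limited peak to an intensity profile taken
perpendicular to the cell surface.  Fitting each peak with a Gaussian plus
an error-function background step (the convolved inside/outside intensity
asymmetry) and correcting the chromatic shift between channels gives

    h = (c_outer − c_inner) − shift · n̂

with ~10–20 nm precision at a ~200 nm PSF, and ~500 nm resolution along the
surface.

**Mechanics.** Releasing turgor (laser ablation) relaxes the wall
elastically; thin-shell force balance converts strains into moduli:
`Y_side/P = R/(h·strain)` on the cylinder, `Y_tip/P = R_t/(2·h·strain)` at
the hemispherical tip.  Turgor itself comes from an osmotic chain
(`c̄₀ = c̃₀ + c_media`, Boyle–van 't Hoff correction with inaccessible
volume fraction β, then `P = (c̄₁ − c_media)·R·T`).

**Dynamics.** With `EV` the apical vesicle pool, `c` wall remodelers and `G`
the plastic strain rate:

    dh/dt    = γ·EV − G·h
    G        = μ·c·(PR/(Yh) − ε)₊
    dEV/dt   = ϕ·G − α·EV
    d(hc)/dt = β·EV − G·h·c

The strain-rate feedback `ϕ·G` is essential: the model has a single growing
steady state (h\* = γϕ/α — thickness homeostasis, independent of turgor and
stiffness), stable only with this feedback, and it reproduces branching
start-up, osmotic-shock arrest and recovery, secretion-block thickening, and
obstacle contact.  A synthetic-data module renders phantom hyphae with known
ground truth so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from hyphoshell import synthetic_data as sd, wallmap as wm
from hyphoshell import wallmech as wme, tipmodel as tm

# turgor from the osmotic chain
est = wme.turgor_from_osmotics(c0_tilde=0.808, c_media=0.112,
                               volume_ratio=0.70, beta_osm=0.22)
print(f"c1_bar = {est.c1_bar:.3f} M, P = {est.P:.2f} MPa")

# tip Young's modulus from an ablation measurement
yp = wme.modulus_ratio_tip(Rt1=1200.0, h_tip=65.0, tip_strain=0.13)
print(f"Y_tip/P = {yp:.1f} -> Y_tip = {yp*est.P:.0f} MPa")

# calibrated model steady state
ss = tm.steady_state(tm.CALIBRATED_WT)
print(f"h* = {ss.h_star:.0f} nm, G* = {ss.G_star:.2f}/min")

# measure a rendered phantom with known truth
img = sd.render_image(sd.make_phantom(h_nm=80.0), sd.ImagingSpec(seed=1))
tmap = wm.map_thickness(img)
ok = tmap.quality_flag
print(f"recovered h = {np.nanmean(tmap.h[ok]):.1f} "
      f"+/- {np.nanstd(tmap.h[ok]):.1f} nm")
```

prints

```
c1_bar = 0.566 M, P = 1.13 MPa
Y_tip/P = 71.0 -> Y_tip = 80 MPa
h* = 65 nm, G* = 0.30/min
recovered h = 81.9 +/- 2.2 nm
```

`P = 1.13 MPa` is the turgor implied by the printed osmotic inputs (1.1 MPa
at two significant figures; β = 0 gives 1.3 MPa).  The phantom's true wall
is 80 nm: the pipeline recovers it within ~2 nm on average under realistic
noise, comfortably inside the method's 10–20 nm precision envelope.

A command-line interface mirrors the library:

```bash
hyphoshell make-phantom --thickness 90 --seed 2 --out phantom.tif
hyphoshell map-thickness --image phantom.tif --out thickness.csv
hyphoshell estimate-turgor --c0-tilde 0.808 --c-media 0.112 \
    --volume-ratio 0.70 --beta 0.22 --out turgor.json
hyphoshell simulate-model --scenario branching --out traj.csv
hyphoshell analyze-timelapse --traces traj.csv --out summary.json
```

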