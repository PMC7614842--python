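# fdcret

Kinetics of immune-complex (IC) retention on follicular dendritic cells
(FDCs), for immunologists and modellers studying how antigen persists in
B-cell follicles during the germinal-center reaction.

Antigens reach FDCs as complement-decorated immune complexes and are held
by CR2 (CD21/CD35) receptors binding the C3d fragments on the antigen.
Each individual CR2–C3d bond is weak (BLI gives k_off = 0.15 s⁻¹, a ~7 s
bond lifetime), yet FDCs display intact antigen for weeks.  This package
implements the quantitative machinery that connects those two facts:

- **`bond_kinetics`** — a one-step (birth–death) master equation for the
  number *m* of closed bonds holding an IC on a membrane patch,

  dP_m/dt = r(m+1) P_{m+1} + g(m−1) P_{m−1} − (r(m) + g(m)) P_m,

  with unbinding rate r(m) = m·k_off, rebinding rate g(m) = C(m)·k_on and
  all-to-all configuration count C(m) = (n_R − m)(n_L − m); m = 0 is
  absorbing (g(0) = 0, the IC is lost).  The survival probability
  S(t) = Σ_{m≥1} P_m(t) is averaged over a Poisson distribution of
  per-patch receptor counts n_R, and ⟨S(t)⟩·⟨n_R⟩ is the mean IC surface
  level at a given CR2 density.  `calibrate_rebinding` fits (k_on, n_L) to
  measured IC half-lives at known CR2 densities.
- **`gillespie`** — a seeded stochastic-simulation oracle for the same
  chain, used to cross-validate the deterministic solver.
- **`binding_fits`** — 1:1 Langmuir global kinetic fits and equilibrium
  hyperbola fits of BLI sensorgrams, fluorescent-bead calibration of
  quantitative flow cytometry (MFI → molecules/µm²), single-exponential
  decay fits of in-vivo antigen levels, and the ELISA titer transform.
- **`imaging`** — concentric-shell quantification of antigen distribution
  across FDC networks in confocal images: mask, label, six equal-depth
  shells per follicle (outermost = background), dual-normalized five-shell
  radial profiles, and thresholded 3D network volumes.
- **`synthetic`** — seeded generators for all of the above (follicle
  images with known radial profiles, decay tables driven by the forward
  model, sensorgram and bead panels), so the whole pipeline is testable
  without any experimental data.
- **`cli`** — `fdcret` command-line entry points wrapping the modules.

## Worked example

The central scientific result: a modest (1.5-fold) difference in CR2
surface density produces a dramatic difference in antigen retention.

```python
import fdcret as f

cal = f.calibrate_rebinding(
    anchor_densities=[250.0, 375.0],              # CR2 molecules / um^2
    anchor_half_lives=[1.2 * 3600, 1.5 * 86400],  # measured: 1.2 h and 1.5 d
    k_off=0.15,                                   # BLI single-bond off-rate
)
p = cal.params
print(f"calibrated: n_L = {p.n_L}, k_on = {p.k_on:.3g} s^-1, "
      f"patch area = {p.patch_area} um^2")
print(f"model half-life at 250 /um^2: {cal.fitted_half_lives[0] / 3600:.2f} h")
print(f"model half-life at 375 /um^2: {cal.fitted_half_lives[1] / 86400:.2f} d")

t14 = 14 * 86400.0
lev = [f.mixture_level_at(p, f.density_to_mean_nR(d, p.patch_area), t14)[0]
       for d in (250.0, 375.0)]
print(f"day-14 IC level fold (375 vs 250): {lev[1] / lev[0]:.2f}")
```

prints

```
calibrated: n_L = 6, k_on = 0.434 s^-1, patch area = 0.018 um^2
model half-life at 250 /um^2: 1.20 h
model half-life at 375 /um^2: 1.49 d
day-14 IC level fold (375 vs 250): 7.31
```

Reading: with six effective C3d sites per IC and a calibrated rebinding
rate of 0.43 s⁻¹ per open configuration, raising CR2 from 250 to 375
molecules/µm² (the difference between peripheral and central FDCs)
lengthens the IC half-life ~30-fold and leaves ~7-fold more antigen on the
membrane two weeks after immunization — rebinding makes retention
superlinearly sensitive to receptor density.

The same computations are available from the shell, e.g.

```
fdcret calibrate --anchors 250:4320,375:129600 --out calibration.yaml
fdcret simulate-retention --params calibration.yaml --densities 250,375 --out curves.csv
fdcret generate-synthetic --kind follicle-uniform --seed 1 --out follicle.tiff
fdcret quantify-shells --image follicle.tiff --pixel-size 4 --out profiles.csv
```

## Layout

```
src/fdcret/        library modules
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    model description, numerical choices, limitations
```
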