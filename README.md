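# islandmech

Force and motion in confined collective cell migration: a Python toolkit
for measuring cell velocities, cell–substrate tractions and monolayer
stresses in circular micropatterned epithelial islands on soft elastic
substrates.

Epithelial sheets move collectively — swirling, oscillating, pulling on
their substrate and on each other. Linking that motion to the forces that
drive it requires three measurements from the same time-lapse experiment:
the velocity field of the cells, the traction field they exert on the gel,
and the stress tensor carried within the sheet. `islandmech` implements the
full measurement chain for the confined-island geometry, plus a
ground-truthed synthetic island so every inverse step can be verified
end-to-end. It is aimed at groups analysing traction-microscopy time-lapse
data of confined monolayers and at theorists who want a transparent,
testable reference implementation to compare models against.

## The measurement chain

1. **Cell velocities** — subset image correlation between consecutive
   phase-contrast frames (48 px subsets, 12 px spacing), and substrate
   displacements between particle images and a traction-free reference
   (32 px subsets, 8 px spacing): normalized cross-correlation with
   Gaussian subpixel peak interpolation and an optional iterative
   warp-and-recorrelate refinement.
2. **Tractions** — Fourier-transform traction microscopy on the elastic
   half-space. Mode by mode, the gel-surface displacement is
   u(k) = G(k)·T(k) with the Boussinesq kernel

       G(k) = 2(1+ν)/(E k³) [[(1−ν)k² + ν ky²,  −ν kx ky],
                             [−ν kx ky,          (1−ν)k² + ν kx²]]

   inverted exactly (optional Tikhonov regularization), followed by a
   minimal least-squares correction that restores force and moment
   equilibrium.
3. **Monolayer stresses** — plane-stress finite elements on the island
   mask solve the in-plane force balance ∇·σ = T/h, closed by
   compatibility and a linear constitutive law
   σij = (K1 − 2/3 K2) tr(ε̇) δij + 2 K2 ε̇ij whose magnitude and units
   cancel from the result — only a Poisson-like ratio ν_m matters, and
   only weakly. Principal stresses σ1 ≥ σ2, stress-ellipse descriptors and
   the contractile tension (σ1+σ2)/2 come out per grid site.
4. **Trajectories and validation** — forward-Euler trajectory integration
   through the velocity fields, traction-confinement and edge-direction
   checks, and drug-response normalization of contractile-tension series.

Sign convention throughout: `T` is the traction the cells exert on the
substrate, so a cohesive contractile island pulls radially **inward** at
its edge while the sheet itself is under positive (tensile) stress.

## Worked example

```python
import islandmech as im

# a ground-truthed synthetic island: 52 µm radius at 0.65 µm/px on a
# 6 kPa gel (desk-scale stand-in for the 1 mm experimental island)
island = im.synthesize_island(n=256, seed=1)

# traction microscopy round trip on the exact displacement field
disp = im.fttc_forward(island.traction, island.substrate)
back = im.fttc_inverse(disp, island.substrate)

# monolayer stress recovery
mesh = im.build_mesh(island.domain)
stress = im.principal_stresses(
    im.solve_stress(island.traction, mesh, island.monolayer))
_, tension = im.contractile_tension(stress)

print(im.rms_traction_ratio(back, island.domain))     # 1.8e-15
print(im.edge_traction_sign(island.traction, island.domain))  # -96.6 Pa
print(tension)                                        # 197.6 Pa
```

The three numbers say: the reconstructed tractions are entirely confined
to the cell-covered region (outside/inside RMS ratio at machine
precision); the cells pull radially inward at the island edge at ~100 Pa;
and the sheet carries ~200 Pa of contractile tension — the magnitudes
typical of epithelial islands on soft gels.

The `examples/` directory walks through each capability as a short script
(`01_synthesize_island.py` … `07_full_pipeline.py`); the full image-based
pipeline — speckle rendering → image correlation → traction inversion →
stress recovery → validation report — is
`python examples/07_full_pipeline.py`, which prints

```
validation: PASS
  rms_traction_ratio: 0.07879
  edge_radial_traction_Pa: -75.53
  contractile_tension_Pa: 211.8
```

A thin CLI mirrors the stages for shell use:
`islandmech {synth,dic,traction,stress,kinematics,validate,run}`.

Experimental datasets in the public island-folder layout (particle stack
`c1_island#.tif`, cells `c2_island#.tif`, trypsin reference
`c1_tryp_island#.tif`, mask `domain.tif`, plus MAT-file results) are read
through `islandmech.io`; the pipeline accepts such a folder in place of a
synthetic bundle.

## Layout

```
src/islandmech/
  domain.py      island geometry, monolayer and substrate parameters
  fields.py      gridded vector / strain-rate / stress containers
  synthetic.py   ground-truthed island generator (closed-form chains)
  dic.py         subset image correlation
  traction.py    half-space forward/inverse operators, equilibrium
  msm.py         plane-stress FEM stress recovery, principal stresses
  kinematics.py  radial decomposition, trajectory integration
  validate.py    confinement / sign / normalization metrics
  io.py          TSV tables, TIFF, MAT files, island records
  pipeline.py    end-to-end orchestration with run manifests
  cli.py         thin command-line interface
docs/methods.md  model assumptions, conventions, numerical choices
```
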