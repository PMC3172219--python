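# actinmesh

Quantitative analysis of cortical F-actin architecture and lytic-granule
access at immune synapses imaged by super-resolution (3D-SIM) microscopy.

Natural killer (NK) cells kill by secreting lytic granules — rigid
secretory lysosomes ~100–800 nm across — through the cortical actin layer
at the immune synapse. At ~100 nm resolution the actin is not cleared from
the synapse centre on activation; the mesh *opens up*, and whether a
granule can reach the membrane becomes a geometric property of the gaps.
`actinmesh` is a pipeline for cell biologists and imaging scientists who
want that geometry quantified reproducibly:

* **mesh holes** — connected actin-negative components within the central
  synapse, with per-hole areas, blue→red area heat maps, and the summary
  gap width `w = sqrt(mean hole area)`;
* **penetrability** — the Euclidean distance transform `D(x)` of the hole
  set thresholded by the granule radius ρ (a pixel is penetrable iff its
  clearance to actin is ≥ ρ), giving per-diameter penetrable fractions and
  connected penetrable domains banded by the largest granule they admit;
* **granules** — 3D spot detection in z-stacks, Gaussian-fit diameters with
  quadrature PSF correction `d = sqrt(FWHM² − FWHM_psf²)`, height strata,
  lateral distances to penetrable domains, and the docking odds ratio
  `OR = [p/(1−p)] / [f/(1−f)]` (`p`: fraction of granules on penetrable
  pixels per axial bin; `f`: penetrable area fraction);
* **geometry & dynamics** — peripheral-ring detection and sizing from
  radial intensity profiles, ring-relative particle statistics, MTOC
  localisation, microcluster tracking (speeds, centripetality), Pearson
  colocalisation `R_r`, and 1–2 component Gaussian FWHM resolution fits;
* **synthetic data** — generators for exact binary mesh fixtures and for
  realistic noisy synapse images, stacks and movies with ground-truth
  tables, so every measurement is validated against known truth.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Simulate an activated synapse (opened-up mesh, mean hole area 0.25 µm²,
bright peripheral ring) and run the core pipeline:

```python
from actinmesh import *
from actinmesh.synth import ACTIVATED_PRESET

spec = SimulationSpec(seed=42, **ACTIVATED_PRESET)
img, truth = simulate_actin_image(spec)

cell   = segment_cell(img)
ring   = detect_ring(img, cell)
region = central_region(ring, cell, img.pixel_size_nm)
actin  = segment_actin(img, "otsu", region=region)
holes  = extract_holes(actin, region)
dist   = distance_map(actin)
curve  = penetrable_fraction_curve(dist, region, [100, 250, 500])

print(f"ring: inner {ring.inner_diameter_um:.2f} um, outer {ring.outer_diameter_um:.2f} um")
print(f"central region: {region.area_um2:.1f} um^2")
print(f"holes: n={holes.n_holes}, mean area {holes.mean_area_um2:.3f} um^2, "
      f"mean width {holes.mean_width_nm:.0f} nm (truth mean {truth.area_um2.mean():.3f} um^2)")
for _, row in curve.iterrows():
    print(f"penetrable by {row.diameter_nm:.0f} nm granule: {row.fraction_pct:.1f} %")
```

which prints:

```
ring: inner 7.98 um, outer 9.96 um
central region: 50.0 um^2
holes: n=60, mean area 0.246 um^2, mean width 496 nm (truth mean 0.244 um^2)
penetrable by 100 nm granule: 19.8 %
penetrable by 250 nm granule: 7.9 %
penetrable by 500 nm granule: 0.9 %
```

The detected ring (8.0/10.0 µm truth) defines a 50 µm² central region; the
measured mean hole area (0.246 µm²) recovers the generator's truth
(0.244 µm²), and the penetrable fraction falls steeply with granule
diameter — the opened mesh admits a 100 nm sphere over ~20% of the centre
but a 500 nm one almost nowhere.

The same stages are available from the shell:

```bash
actinmesh --seed 42 --outdir out synthgen --kind actin --preset activated
actinmesh --outdir out holes out/actin.tiff
actinmesh --outdir out penetrability out/actin.tiff
actinmesh --seed 42 --outdir out run-all      # end-to-end, reproducible
```

Each run writes CSV tables, label/heat-map images and a `manifest.json`
recording every file, its producing stage and the configuration hash.

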