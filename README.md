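# plexcyto

Multiplexed, multi-resolution **image cytometry** for sequential-staining
fluorescence microscopy: inter-round rigid registration, single-cell
segmentation and measurement, DNA-damage-foci / RNA-spot counting,
flow-cytometry-style gating, and conversion of gated cells back into
microscope **stage coordinates** for targeted re-acquisition.

## The problem

Cyclic immunofluorescence protocols (stain → image → strip → re-stain)
build up tens of markers on one tissue slide, but every round the slide is
re-mounted, so each acquisition is rigidly displaced from the last.  A
single experiment mixes magnifications too: a fast low-magnification *map*
locates tissue-microarray cores, cell-resolution imaging measures marker
expression, and diffraction-limited imaging (widefield or confocal
Z-stacks) resolves subcellular objects such as γH2A.X damage foci or
single-molecule RNA-FISH spots.  Turning all of that into one per-cell
database — and driving the microscope back to the cells an analysis
selects — requires:

1. **Registration.** The inter-round displacement is a rigid
   roto-translation `T = (θ, t)`.  It is estimated coarse-to-fine on the
   nuclear channel (phase-correlation translation + bounded 1D rotation
   search, iterated to convergence), optionally on downscaled data and
   then re-expressed at full resolution.  Rounds at different
   magnifications are first resampled by the metadata pixel-size ratio.
2. **Segmentation.** DNA-based nucleus labels with watershed decomposition
   of touching clusters; cell bodies grown from each nucleus, bounded by
   the cytokeratin/membrane territory and a maximum radius; puncta by a
   locally adaptive band-pass with peak deblending.
3. **Cytometry.** One row per cell: area, circularity
   `4πA/P²` (1 for a circle, → 0 for elongated cells), centroid in image
   pixels and stage µm, per-channel Total/Mean intensity (exact integer
   accumulation), per-spot-channel count / summed intensity / mean per
   spot; spots also reported as an owner-free population.
4. **Gating & targeting.** Threshold/rectangle/polygon gates combined with
   AND/OR/NOT, cross-tabulations, population masks, and position-list
   export: `stage = origin + signed pixel offset × pixel size`, corrected
   through the estimated inter-round transform.

No public dataset accompanies this kind of experiment, so the package
includes a **synthetic tissue generator** with complete ground truth
(nucleus/cell masks, marker classes, per-object puncta, per-round
transforms, per-magnification scales) against which every stage is tested.

## Worked example

One command generates a two-round synthetic sample (round 1: DAPI / CK8 /
KI67 at cell resolution plus a 4x-like map; round 2: the same slide
re-mounted with a known misplacement, carrying γH2A.X and 53BP1), runs the
whole pipeline, and scores the result against the generator's ground
truth:

```sh
plexcyto demo --outdir demo_out --seed 0
```

or `python -c "import plexcyto; plexcyto.demo(seed=0, outdir='demo_out')"`.
Key numbers from the report it prints (seed 0):

```
"n_cells_segmented": 140          # the scene contains 140 cells
"gates": {"KI67_positive": {"n_members": 52, "fraction": 0.371}}
"relocation": {
  "fraction_within_2_highres_px": 1.0,
  "median_error_20x_px": 0.048
}
"stack_alignment": {"true_z_offset": 1, "recovered_z_offset": 1,
                    "lateral_error_px": 0.071}
```

Reading: all 140 generated cells were segmented; 52 cells (37%) pass the
KI67 mean-intensity gate; after re-registering the round-2 map, every
gated cell's predicted round-2 position lands within 2 high-resolution
(60x-like) pixels of its true location — the median error is 0.05
cell-resolution pixels — and the 3D stack alignment recovers the applied
one-plane axial offset exactly with a 0.07 px lateral residual.  Artifacts
(registered images, label masks, the cell database CSV, gate sub-tables,
position lists, a JSON run report) are written under `demo_out/run/`.

## Layout

| module | role |
|---|---|
| `plexcyto.synthetic` | ground-truth scene generator, round/stack renderer, TMA map |
| `plexcyto.io` | OME-TIFF + sidecar metadata, cell database CSV, position lists, 8-bit display scaling |
| `plexcyto.registration` | `RigidTransform` algebra, coarse-to-fine estimation, cross-magnification, Z-stacks |
| `plexcyto.mosaic` | tile planning (10% default overlap), feathered stitching with pairwise refinement |
| `plexcyto.segmentation` | nuclei, cell bodies, puncta detection and cell assignment |
| `plexcyto.cytometry` | per-cell/per-spot measurement records, cross-round merge |
| `plexcyto.gating` | gate expressions, cross-tabs, population masks, coordinate retrieval |
| `plexcyto.targeting` | stage mapping, TMA dearraying, ROI propagation, focus surface, position export |
| `plexcyto.pipeline` / `plexcyto.cli` | config-driven orchestration and the `plexcyto` command |

See `docs/methods.md` for the models, parameter choices, and limitations.
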