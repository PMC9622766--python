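# lymphoquant

Quantitative image analysis of lymphedematous mouse skin.

Secondary lymphedema — chronic limb swelling after lymph-node surgery
and/or irradiation — remodels the skin: lymphatic capillaries that
normally sit around hair follicles in the papillary dermis spread into
the deep reticular dermis, collagen shifts toward thick scar-type
fibers, and matricellular proteins (periostin, tenascin-C) accumulate.
`lymphoquant` implements the computerized readouts used to quantify
these changes on whole-section histology images of the mouse hind-limb
model, for researchers who have section scans plus a basal-layer
annotation and want reproducible numbers instead of interactive
measurements.

## What it computes

**Stain segmentation.** For a stain whose dominant channel is *C* with
the other channels *C₁, C₂*, contrast is enhanced with the excess-color
transform

&nbsp;&nbsp;&nbsp;&nbsp;E = 2·C − C₁ − C₂

(e.g. `2R − G − B` for a red chromogen), and the map is binarized with
an automatic threshold maximizing Otsu's between-class variance.
Explicit add/remove rasters reproduce manual corrections.

**Depth-referenced spatial profiling.** Each dermal pixel's depth is
its Euclidean distance (µm) to the basal epithelial layer polyline.
Stained pixels are binned by depth into a spatial distribution curve
whose summaries are the *integrated area* (total stained area, the
area under the curve, µm²) and *P90* (the depth below which 90 % of
the cumulative stained area lies). Profiles split at the
papillary/reticular junction depth, conserving total area exactly.

**Collagen scar index.** On polarized-light picrosirius red images,
pixels are classified by HSV hue into thick (red-orange birefringent,
mainly type I collagen) and thin (green, mainly type III) fibers; the
scar index is the thick/thin area ratio per dermal compartment.

**ICG clearance.** Indocyanine-green fluorescence series (sampled at
0, 1, 3, 5, 7 h) are summarised by the trapezoidal area under the
intensity–time curve between 1 h and 5 h; a larger AUC means impaired
lymphatic drainage.

**Morphometry and statistics.** Paw swelling is normalized per animal
as (T/Tc)×100 (operated over control paw thickness); layer thickness
is measured at five stations perpendicular to the band's axis; group
effects are summarised as ratios of medians and tested with binwise
Mann–Whitney curve comparison, Kruskal–Wallis + Dunn, two-way ANOVA +
Tukey, and Spearman correlation.

A synthetic-data module (`lymphoquant.synthetic`) generates skin
sections, polarized scenes, ICG series and four-group paw cohorts with
exact ground truth, so every stage is testable as a parameter-recovery
problem without access to slide scans.

## Worked example

Quantify the lymphatic stain on a synthetic control section (5,000
capillary-sized blobs confined to the papillary dermis, 1 µm/px):

```python
import lymphoquant as lq
from lymphoquant import synthetic as syn

spec = syn.control_scene_spec(seed=7, blob_count=5000)
section, truth = syn.generate_skin_section(spec)

mask = lq.segment_stain(section, channel="R", marker="Lyve-1")
dmap = lq.depth_map(section)
profile = lq.depth_profile(mask, dmap, bin_width_um=10.0)
papillary, reticular = lq.split_compartments(profile, section.junction_depth_um)

print(f"threshold            : {mask.threshold_used:.1f}")
print(f"integrated area (um2): {profile.integrated_area_um2:.1f}")
print(f"P90 (um)             : {profile.p90_um:.1f}")
print(f"papillary area (um2) : {papillary.integrated_area_um2:.1f}")
print(f"reticular area (um2) : {reticular.integrated_area_um2:.1f}")
print(f"true area (um2)      : {truth.total_stain_area_um2:.1f}")
print(f"true P90 (um)        : {truth.true_p90_um:.1f}")
```

prints

```
threshold            : 122.5
integrated area (um2): 61554.0
P90 (um)             : 292.0
papillary area (um2) : 61554.0
reticular area (um2) : 0.0
true area (um2)      : 61554.0
true P90 (um)        : 291.6
```

The automatic threshold (122.5) separates the stain from background on
the excess-red map; the segmented area equals the rendered ground
truth exactly on a noise-free scene, the P90 of ~292 µm sits in the
225–300 µm band expected when capillaries stay in the papillary
dermis, and no stained area falls below the 350 µm junction.

## Command line

```bash
lymphoquant simulate --out cohort/ --seed 5            # synthetic 4-group cohort
lymphoquant run --input-dir cohort/ --out results/     # segment + profile + stats
lymphoquant segment IMG.png IMG.json --out mask.png    # single stages
lymphoquant profile IMG.png IMG.json --out profile.csv
lymphoquant scar-index IMG.png IMG.json --out scar.csv
lymphoquant clearance icg.csv --out auc.csv
lymphoquant morphometry paw.csv --out paw_norm.csv
lymphoquant stats summary.csv --out folds.csv
```

`run` writes per-section masks, a long per-bin profile table, a
summary table (integrated area, P90, compartment areas), LD-vs-control
binwise statistics, median fold changes and a JSON manifest recording
every parameter and seed; re-running with the same config and inputs
reproduces byte-identical CSVs.

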