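# Methods

## Scope and model of the data

`lymphoquant` quantifies stained structures on RGB whole-section
images of mouse hind-limb skin. The tissue model is a stack of three
compartments below a basal epithelial layer: epidermis above the
basal layer (excluded from all profiles), papillary dermis from the
basal layer down to a configurable junction depth, and reticular
dermis beneath. All spatial quantities are referenced to the basal
layer, supplied as an ordered polyline annotation in pixel
coordinates; the package does not attempt to detect it, because on
real sections it is drawn by a histologist and on synthetic sections
it is emitted by the generator as ground truth.

## Segmentation

The excess-color transform `E = 2·C − C₁ − C₂` (integer arithmetic,
range −510…510, never clipped before thresholding) enhances the
contrast of a stain whose dominant channel is `C`. It is invariant to
adding a constant to all three channels, which suppresses overall
brightness variation. Immunofluorescence channels are handled
identically through the dominant emission channel — one pipeline for
all stains.

Binarization uses Otsu's criterion: the threshold maximizing the
between-class variance of the masked map values. Two numerical
choices matter:

* **Candidate levels.** When the map has at most 256 distinct values
  (always true for integer excess-color maps) the criterion is
  evaluated exactly over the unique values; only genuinely continuous
  maps are first quantized to a 256-bin histogram. This makes the
  result identical to an exhaustive search over all candidate
  thresholds, which the test suite checks on random two-population
  histograms.
* **Threshold placement.** The returned threshold is the midpoint
  between the largest value of the low class and the smallest value
  of the high class, so the strict rule "stained iff value >
  threshold" reproduces the variance-maximizing partition exactly. A
  bin-center threshold (as some library implementations return) can
  misassign values lying above the center of their own bin; on
  quantized maps whose background concentrates on a single level this
  flips the entire background into the mask.

Ties at the threshold are unstained, everywhere. Manual correction is
represented as explicit add/remove rasters applied as
`(mask ∪ add) \ remove`; a pixel present in both rasters is rejected
as ambiguous, and any non-empty correction flags the mask as manually
corrected. This keeps corrections versionable and reproducible.

## Depth profiling

Depth is the exact Euclidean distance from a pixel center to the
nearest point of the basal polyline (segment-wise projection, not a
rasterized distance transform), scaled by the pixel size. With a
curved basal layer the nearest-point distance is the natural reading
of "distance from the basal layer"; the metric is recorded in the run
manifest. Pixels on the epidermal side of the polyline are flagged
and excluded from every profile.

Stained-pixel depths are binned into uniform bins (default 10 µm,
roughly two orders of magnitude below the P90 scale of interest;
configurable). Each bin holds stained pixel count × pixel area, so
the curve is an absolute stained area per depth bin (µm²) and its sum
— the *integrated area* — is the total stained area. A
tissue-normalized variant is a flag away but absolute area is the
default, since the quantity of interest is the global extent of the
stained region.

**P90 convention.** P90 is the depth below which 90 % of the
cumulative stained area lies. When a profile is built directly from a
mask, the unbinned pixel depths are retained and P90 is their exact
empirical 0.9 quantile — no bin-grid artifacts. A profile known only
through its curve (a mean curve, a compartment split) uses the same
empirical-quantile convention carried to binned data: each bin's area
is treated as sitting at the bin's lower edge and P90 is the
generalized inverse of that step CDF. In particular a point mass
rendered into bin [d, d+w) reports P90 = d, not an interpolated value
inside the bin; within-bin linear interpolation was considered and
rejected because it shifts a point mass at a bin edge by up to one
bin width and disagrees with the empirical quantile that the raw
pixel depths define. An empty profile carries an undefined (NaN) P90
and is flagged rather than raising.

Compartment splitting assigns bins below the junction depth to the
papillary profile and the rest to the reticular one; a straddling bin
is divided pro-rata by width, so papillary + reticular integrated
areas equal the whole-dermis integrated area to machine precision.

## Scar index

Polarized-light picrosirius images are classified in HSV. Defaults:
thick (red-orange) hue ∈ [0°, 50°] ∪ [340°, 360°], thin (green) hue ∈
[70°, 160°], saturation ≥ 0.2, value ≥ 0.1 — conventional picrosirius
polarization bands, fully configurable and recorded in the output.
Yellow hues between the windows stay unassigned rather than being
forced into a class, and overlapping windows are rejected at
validation. The scar index is thick/thin area per compartment; a
compartment with no thin signal yields an explicitly undefined result
instead of an infinite ratio.

## ICG clearance

The 1–5 h AUC is a plain trapezoidal integral of the measured ROI
mean intensities, with linear interpolation at the window ends when
1 h or 5 h is not a sample point. With five timepoints, fitting a
decay model would add assumptions without adding information; the
trapezoid on measured points is exactly "the area under the curve".
No background subtraction or t = 0 normalization is applied by
default; both exist as options.

## Morphometry

Paw swelling is (T/Tc)×100 per animal — unit-free, so caliper units
cancel. Layer thickness is measured at five stations along the band's
principal axis (PCA of the mask coordinates): at each station the
band's extent perpendicular to the axis within a thin slab is
converted to µm. Stations sit at stratum centers; an optional seed
jitters them within their stratum. Even spacing is reproducible and
unbiased along the band; the PCA frame makes the measurement
orientation-independent (rotated copies agree within 5 % in tests).
Fold changes between groups are ratios of medians, consistent with
median ± IQR group summaries.

## Statistics

* Binwise curve comparison: per depth bin, a two-sided Mann–Whitney U
  on the per-section bin areas; exact null when the combined sample
  is ≤ 20 without ties, tie-corrected normal approximation otherwise.
  A bin where every value is identical carries no evidence: p = 1.
  Raw p-values are the primary output; an optional
  Benjamini–Hochberg column is offered because dozens of bins are
  tested, and it is clearly labelled as an addition.
* Kruskal–Wallis with Dunn's post-hoc: Dunn's z uses the
  tie-corrected pooled-rank variance; pairwise p-values are
  Bonferroni-adjusted by default (Holm and unadjusted available).
  Dunn's test is implemented in-package and validated against rank
  arithmetic and a 1,000-replicate type-I-error simulation (rejection
  rate within [0.03, 0.07] at α = 0.05).
* Two-way ANOVA (limb × group) with Tukey HSD over the cells,
  delegated to statsmodels; results match an explicit sums-of-squares
  decomposition on balanced designs in the tests. Zero-variance data
  return F = 0, p = 1 flagged degenerate; a perfect fit with effects
  (zero residual variance) is likewise flagged rather than reported
  as an unbounded F.
* Spearman correlation reports rho, rho² and two-sided p; constant
  input is flagged undefined.

## Synthetic data: what it emulates and what it does not

The generator renders: an epidermis band over dermis; a flat basal
polyline; circular stain blobs with centroid depths drawn from a
configurable distribution (uniform, point mass, mixtures), clipped at
the basal layer so stain never invades the epidermis; hair-follicle
profiles confined to the papillary dermis; additive Gaussian pixel
noise clipped to [0, 255] (the simplest model that stresses
thresholding); polarized scenes as single-pixel fiber sites on a
near-black background with hues drawn inside the thick/thin windows;
single-exponential ICG decay sampled at 0/1/3/5/7 h; and four-group
paw cohorts (default n = 8, 7, 11, 13) where the operated paw is a
per-group fold of the control paw. Ground truth records exact
rendered areas, centroid depths (blob depth is measured at the
centroid — unambiguous for scoring a point process) and closed-form
AUCs. All generators are bitwise deterministic given their seed.

Deliberately absent: photorealistic histology texture, staining
chemistry, scanner optics, 3-D structure, spatially correlated noise
and out-of-focus blur. Passing recovery tests therefore demonstrates
the correctness of the measurement chain (segmentation → geometry →
statistics) under known truth, not robustness to every artifact of
real slides; on real data the manual-correction pathway exists
precisely because automatic thresholding is imperfect.

Default scene scale is 1 µm/px in tests and examples; the default
`SceneSpec` pixel size is 0.23 µm/px, the physical scanner resolution,
but synthetic scenes at full resolution would be needlessly large for
what they test. Cohort scenes used for fold-change recovery place
blobs without overlap (dart throwing with a grid hash) so the
rendered area scales exactly with blob count, making the generator
ratio the true fold change; an overcrowded non-overlap request fails
loudly naming the constraint.

## Problem sizes

Recovery checks run at 10,000 blobs for P90 (sampling error of the
0.9 quantile ≈ 0.3 %), 5,000 for the control scene, 21 + 21 sections
per fold-change cohort with 300 control blobs per section, 4,000
fiber pixels per polarized scene, and 1,000 replicates for the
type-I-error simulation. These sizes keep every quantity's sampling
noise comfortably inside its acceptance band while the whole suite
and the acceptance script each run in well under a minute of compute.

## Known limitations

* The basal polyline is trusted as given; a misplaced annotation
  shifts every depth.
* Depth is nearest-point distance, which differs from vertical drop
  under strong curvature; both are reasonable, one is chosen and
  recorded.
* Hue-window classification ignores pixel-level mixing of fiber
  colors; partial-volume pixels at fiber boundaries fall to whichever
  window their mixed hue lands in, or to neither.
* Replicate sections from one mouse are analysed per-section; the
  CLI labels outputs per section and per group so a per-mouse
  aggregation can be applied downstream when the design requires it.
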