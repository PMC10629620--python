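# Methods

`gliaquant` packages, as tested and reusable code, the bespoke quantification
procedures of a Drosophila diet/glia study: 3D lipid-droplet segmentation with
tracheal shape filtering and glia-mask intensity extraction, projection/ROI
fluorescence quantification, within-animal injury-clearance normalization,
comparative-CT (ddCt) qPCR fold changes, and the statistical layer that sits
on top of all of them. Because the original measurements come from fly brain
tissue with no deposited raw data, the package ships a synthetic-data
generator with exact ground truth; every claim the tests make is about
recovery of that ground truth or agreement with an independent oracle.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)`, 0-based, half-open ranges everywhere. Voxel
spacing `(dz, dy, dx)` is metadata in micrometres, default `(0.3, 1.0, 1.0)`:
the 0.3 um z interval is the acquisition step of the study design; lateral
pixel size is unspecified there and left configurable. Spacing is never read
from TIFF tags (tag conventions vary across vendors). Intensities are
promoted to float64 on load with **no rescaling**, since every downstream
readout is an integral of raw intensity.

## Lipid-droplet pipeline (`droplet3d`)

1. **Otsu binarization in 3D.** The threshold maximizes the between-class
   variance `w0*w1*(mu0-mu1)^2` over a 256-bin histogram spanning the
   observed min–max range of the whole volume (not per slice). The returned
   value is a bin *edge*; voxels strictly above it are foreground. Ties break
   toward the lowest maximizing edge. One subtlety: every edge inside an
   empty histogram gap induces the same partition of the data as the gap's
   lower edge and hence ties with it *exactly* in exact arithmetic, while the
   two floating-point evaluation orders (vectorized cumulative sums vs a
   per-candidate scan) can break such ties differently at the 1e-13 level.
   Candidates are therefore restricted to edges directly above a nonempty
   bin, which realizes the lowest-tie rule robustly; the implementation then
   agrees bit-for-bit with a brute-force exhaustive scan.
2. **Connected components** via `scipy.ndimage.label`, 26-connectivity by
   default (6 and 18 available) — the default 3D practice of the environment
   the original pipeline was built in.
3. **Shape.** Per object, the principal-axis lengths are
   `c * sqrt(eigenvalues)` of the voxel-coordinate covariance matrix with a
   per-coordinate `1/12` variance regularization (the second moment of a unit
   voxel, so a single voxel is isotropic with ratio exactly 1). The scale
   constant is `c = 2*sqrt(5)`: a solid ellipsoid with semi-axis `a` has
   covariance eigenvalue `a^2/5`, so this `c` recovers the full axis length
   `2a` — the ellipsoid-equivalent convention of MATLAB `regionprops3`.
   The elongation measure `axis_ratio = L1/L3` is independent of `c`, so the
   filter below cannot depend on this choice. Shapes are measured in voxel
   units by default (the 5,000-voxel volume cut implies voxel-space
   operation); a physical-unit mode exists but is non-canonical because the
   0.3 um z anisotropy changes ratios.
4. **Tracheal filter.** Objects with `axis_ratio > 5` **or**
   `voxel_count > 5000` are removed; "greater than" is strict, so boundary
   values survive. The filter runs on the whole-volume object set *before*
   mask intersection, mirroring the procedure's stated order.
5. **Glia mask and extraction.** The manually drawn antennal-lobe polygon is
   propagated along z into a prism; a voxel is in the mask iff its pixel
   center lies inside the polygon (even-odd rule). Each kept object
   contributes the sum of lipid-channel intensities over its intersection
   with the mask; empty intersections contribute 0 but stay in the table.
   Both the **sum** over kept objects (canonical per-brain readout) and the
   mean per object are exported, since the study's figure axis ("mean
   intensity") does not disambiguate the two.

### Point-in-polygon boundary rule

One even-odd ray-casting routine backs the glia mask and polygon ROIs. Its
boundary is half-open (low-y/low-x edges inclusive), so an axis-aligned
integer rectangle contains exactly area-many pixel centers and prism-mask
voxel counts equal polygon area x z-extent exactly. The routine is
hand-rolled because no installed library pins this exact rule; it is
cross-checked against shapely `contains` at off-boundary points. Polygons
must be simple; validity is checked with shapely at construction.

## Synthetic scenes (`synthetic`)

Droplets are solid balls (center-of-voxel inclusion), tubes are unions of
balls swept along a centerline at 0.25-voxel steps; interiors are flat at
`background + peak`. Objects may not overlap (and the random placer also
keeps them non-adjacent, since touching objects would merge into one
connected component). Noise is additive Gaussian clipped at zero — enough to
stress thresholding; no optical PSF, photobleaching, or realistic tracheal
branching is simulated, so passing tests show correct recovery of idealized
structures under noise, not performance on real confocal data (where manual
mask drawing and acquisition variability dominate).

Default stress conditions (used by the validation suite): scenes of
16 x 96 x 96 voxels with 5 droplets (radius 3–4.5, peak 100) inside a central
rectangular glia polygon, 3 tubes (length 40, radius 2, axis ratio > 5 by
construction) outside it, background 10, noise SD 5 (5% of peak). On
noise-free renders the recovered total equals ground truth exactly; at 5%
noise the total is within a fraction of a percent and tube removal is
essentially perfect.

A note on rasterization aliasing: a thin ellipsoid (semi-axes 10, 2, 2)
rasterized with its center *on* a voxel center measures an axis ratio of
~5.55, at a half-voxel offset ~4.5 — grid-aligned placements are the
degenerate extremes. The shape checks therefore average over random
sub-voxel placements (mean ratio ~5.0, as for the continuous ellipsoid),
while asserting exact agreement with brute-force voxel moments for every
individual placement.

## Clearance (`clearance`)

Per fly and day, `ratio = injured / uninjured` — the uninjured side of the
same animal is the endogenous control, so per-animal gain (staining
efficiency, laser power) cancels exactly. Records with `uninjured <= 0` are
flagged unusable, never dropped silently, keeping n auditable; group x day
summaries report empty cells explicitly. The synthetic series holds the
uninjured side at `baseline` and decays the injured side as
`baseline*(1-decay)^day`, so noise-free day-d mean ratios equal
`(1-decay)^d` in closed form. No mechanistic clearance model is fitted.

## qPCR (`qpcr`)

`fold = 2^-ddCt`, `ddCt = dCt_treatment - dCt_control`,
`dCt_g = mean Ct(target, g) - mean Ct(reference, g)`, with replicate
averaging on the Ct (cycle) scale and no outlier rejection. The canonical
fold comes from replicate-mean Cts; per-replicate folds are available for
mean-of-folds summaries (which of the two the study plotted is not stated).
The generator inverts this construction exactly — reference at 20 cycles in
both groups, targets at `dCt = 5` in control, treatment lowered by
`log2(fold)` — so noise-free tables recover any chosen fold to machine
precision, including the 3.4x and 2.0x magnitudes used as reference points.
Only technical-replicate variation is modeled; there is no
biological-replicate error propagation and no primer-efficiency (Pfaffl)
correction.

## Statistics (`stats`)

Welch's unequal-variance t test (two-sided, Welch–Satterthwaite df) for
two-group comparisons; two-way ANOVA (diet x injury with interaction) for the
clearance design, using type-II sums of squares (equal to the balanced-design
decomposition when cells are balanced; the study design is near-balanced and
silent on the convention); Shapiro–Wilk as a normality *screen* that logs a
warning but never switches tests. Significance convention p < 0.05. The
backing routines are scipy and statsmodels; correctness is asserted against
closed-form oracles and calibration simulations (type-I error of Welch's test
0.05 +/- 0.02 over 2,000 null draws; interaction detection and null
specificity of the ANOVA over 100 seeded designs with 12 observations per
cell, an interaction of 3 residual SDs when present). No multiple-testing
correction is applied (none is part of the procedure being packaged).

## Problem sizes and determinism

The validation suite uses 50 random volumes (<= 32^3) for the Otsu oracle,
20 seeded scenes for end-to-end recovery, 100 simulations for noisy ddCt
recovery and per-arm ANOVA calibration, and 2,000 for Welch calibration —
sizes chosen so the full suite completes in well under a minute per stage
while keeping Monte-Carlo bands tight. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical stacks,
tables, per-object CSVs, and summaries.

## Known limitations

- No watershed splitting: droplets that touch merge into one object (the
  generator places objects apart; real dense droplet fields would need it).
- No automated antennal-lobe detection; the mask is polygon-driven by design,
  as in the original manual procedure.
- The tracheal filter is purely morphological; a tube shorter than ~5x its
  radius, or fragmented by noise into compact pieces, passes as droplets.
- Physical-unit shape mode changes ratios under z-anisotropy and is not the
  convention the 5,000-voxel threshold was calibrated for.
- Instrument acquisition (Seahorse OCR/ECAR etc.) is out of scope; only
  plain-table ingestion of numeric outputs is supported.
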