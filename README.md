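# gliaquant

Quantification pipeline for Drosophila diet/glia experiments: how much
neutral lipid sits inside the ensheathing glia around the antennal lobes, how
bright a reporter is inside a fixed ROI, how fast glia clear injured axons,
and how strongly a transcript responds to diet — plus the statistics used to
compare groups.

It is written for researchers who image fly brains on a confocal (multi-page
TIFF stacks, one channel per file) and need the study's bespoke measurements
as reproducible, scriptable code rather than a chain of manual ImageJ/MATLAB
steps.

## What it computes

**3D lipid content** (`gliaquant.droplet3d`). The lipid-stain channel is
binarized in 3D with Otsu's method; connected components (26-connectivity)
are measured for volume V and ellipsoid-equivalent principal-axis lengths
L1 ≥ L2 ≥ L3 (from the eigenvalues of the voxel-coordinate covariance, 1/12
regularized). Objects with L1/L3 > 5 or V > 5,000 voxels are removed — these
are tracheal tubes, not droplets. A manually drawn antennal-lobe polygon is
propagated along z into a prism mask, and the total lipid content is

    T = Σ_kept objects  Σ_{v ∈ object ∩ mask} I(v)

**ROI fluorescence** (`roi_quant`): z-stack summation projections and
mean intensity / integrated density in a rectangular or freehand ROI, with
enforcement that one experiment batch uses one ROI definition.

**Injury clearance** (`clearance`): per-animal ratio
`injured / uninjured` fluorescence over days 1–4 post ablation, with
group × day summaries.

**qPCR** (`qpcr`): comparative-CT fold change `2^-ΔΔCt` normalized to a
reference gene (e.g. alpha-tubulin), replicate means on the Ct scale.

**Statistics** (`stats`): Shapiro–Wilk screening, Welch's t test, two-way
ANOVA (type-II SS), p < 0.05 convention.

Because no raw data is deposited with the study, `gliaquant.synthetic`
generates ground-truthed inputs for every stage — confocal scenes with known
droplets/tubes/mask, clearance time courses with known decay, Ct tables built
to invert to a chosen fold — and the test suite validates recovery against
that truth and against independent brute-force oracles.

## Worked example

```python
import numpy as np
from gliaquant import random_scene, render_scene, run_lipid_pipeline

spec = random_scene(seed=1)            # 5 droplets in-mask, 3 tubes, 5% noise
channels, truth = render_scene(spec)
result = run_lipid_pipeline(channels, spec.glia_polygon)
print("threshold", round(result.threshold, 2))
print("kept", result.n_kept, "filtered", result.n_filtered)
print("total", round(result.total_lipid_content, 1),
      "truth", truth.total_lipid_content)
```

prints

```
threshold 32.46
kept 5 filtered 3
total 110319.4 truth 110330.0
```

The Otsu threshold (32.46) falls between the background (10) and the droplet
interiors (110); all 5 droplets are kept and all 3 tracheal tubes are
filtered out by the shape rule; the recovered total lipid content is within
0.01% of the noise-free ground truth.

The same pipeline runs from the shell on TIFF + polygon files:

```sh
gliaquant lipid3d --lipid lipid.tif --polygon lobes.txt --out results/
gliaquant qpcr --in ct.csv --reference alpha-tubulin
gliaquant clearance --in clearance.csv
gliaquant stats --in measurements.csv
```

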