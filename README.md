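# gliaquant

Quantification of retinal whole-mount fluorescence micrographs:
automatic counting of Iba-1-labelled microglia and Brn3a-labelled
retinal ganglion cells (RGCs), percent-area measurement, per-cell
morphometry (soma and arbor area), and the nonparametric statistics of
a paired-eye, multi-group ocular-hypertension (OHT) study — together
with a synthetic-field generator that provides ground truth for all of
it.

## Why

In laser-induced OHT models, retinal microglia respond with a
stereotyped activation phenotype — higher cell density, larger somata,
retracted process arbors, more vertical processes crossing between the
outer plexiform layer (OPL) and the photoreceptor outer segments (OS)
— and sustained intraocular pressure kills RGCs.  Quantifying those
changes from whole-mount micrographs relies on a simple, robust
counting algorithm: average the z-stack, normalize to the peak pixel,
zero everything below 0.2, segment the surviving support, take each
segment's intensity-weighted center of mass, and merge centers closer
than a minimum distance so no cell is counted twice.  Microglial
coverage in the nerve-fiber/ganglion-cell layer (NFL-GCL) is
measured as the percent of image area above threshold (Iba1-RA), and
RGCs are counted by the same chain with a nucleus-scale minimum
distance.

Animal studies of this design publish group histograms, not images, so
the measurement machinery itself is hard to validate.  `gliaquant`
closes that gap: its generator plants cells with known positions, soma
radii, process tips and activation state in fields of the standard
0.1502 mm² geometry, and every stage of the pipeline is tested against
that ground truth — from exact count recovery to reproduction of the
full qualitative effect pattern in an end-to-end synthetic study.

## Worked example

```python
import numpy as np
from gliaquant import (FieldGeometry, generate_layer_field, count_cells,
                       DetectionParams, measure_field, OHT_PROFILE,
                       mann_whitney_u)

rng = np.random.default_rng(42)
geo = FieldGeometry(n_pixels=512)          # one 0.1502 mm^2 field
field, truth = generate_layer_field(20, layer="OPL", geometry=geo, rng=rng)

det = count_cells(field, DetectionParams(min_distance=12.0))
print(f"planted cells: {len(truth)}, detected: {det.count}")

morpho = measure_field(field, det)
print(f"mean soma area:  {np.mean([m.soma_area for m in morpho]):6.1f} um^2")
print(f"mean arbor area: {np.mean([m.arbor_area for m in morpho]):6.1f} um^2")

oht_field, _ = generate_layer_field(26, OHT_PROFILE, layer="OPL",
                                    geometry=geo, rng=rng)
oht_m = measure_field(oht_field, count_cells(oht_field))
print(f"OHT-like: mean soma {np.mean([m.soma_area for m in oht_m]):.1f} um^2, "
      f"mean arbor {np.mean([m.arbor_area for m in oht_m]):.1f} um^2")

res = mann_whitney_u([14, 15, 13, 16, 15, 14], [19, 21, 18, 22, 20, 19])
print(f"Mann-Whitney U={res.statistic:.0f}, p={res.p_value:.4f} ({res.method})")
```

Output:

```
planted cells: 20, detected: 20
mean soma area:    38.2 um^2
mean arbor area:  734.6 um^2
OHT-like: mean soma 88.8 um^2, mean arbor 365.9 um^2
Mann-Whitney U=0, p=0.0048 (normal_approximation)
```

The detector recovers all 20 planted cells.  The mean soma area of a
baseline field (38 μm² ≈ π·3.5²) reflects the planted radii; under the
OHT-like activation profile somata grow (soma radii × 1.5 → areas
× 2.25) and arbors retract (tip radii × 0.7 → hull areas roughly
halved).  The Mann–Whitney comparison of two made-up per-animal count
samples illustrates the result object: statistic, two-sided p, and the
method actually used (exact enumeration for small tie-free samples,
tie-corrected normal approximation otherwise).

The end-to-end study — generation, quantification of every field,
per-animal aggregation, and the full comparison grid with mean ± SD
summaries, Mann–Whitney/Wilcoxon contrasts and zone-wise ANOVA with
Bonferroni correction — runs from one config:

```bash
gliaquant run-study --out results/study --seed 7
```

writing `groundtruth.csv`, `per_field.csv`, `per_animal.csv`,
`comparisons.csv`, `zone_anova.csv` and a human-readable `report.md`.
`gliaquant generate`, `quantify`, `morpho` and `compare` expose the
individual stages for TIFF inputs.  All synthetic effect magnitudes are
illustrative configuration (see `docs/methods.md`); only the effect
*directions* emulate the biology.

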