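# wormdart

High-content *C. elegans* DART (developmental and reproductive toxicity)
assay pipeline for 24-well microfluidic worm-trap chips.

Adult worms are trapped in tapered microfluidic channels (40 per well, 960
per chip), imaged as 18-slice brightfield z-stacks, and scored for six
endpoints per animal: **body length, area and volume** (developmental) and
**early-, late- and total in-utero embryo counts** (reproductive).
`wormdart` provides the full desk-side counterpart of that workflow:

- a geometric model of the chip (channel taper profiles, chip map, FOV
  planning, image-count accounting for acquisition plans);
- ground-truthed synthetic data generators (rendered channel z-stacks with
  worms and embryos, hierarchical well-plate phenotype tables, 4PL
  concentration-response draws) standing in for raw data that are not
  publicly deposited;
- the image-analysis chain: Laplacian-variance autofocus, fiduciary
  detection, full/partial/none channel classification, classical
  segmentation, and skeleton-based morphometrics with height-integrated
  volume;
- file-based embryo scoring (annotation validation, per-worm counts, audited
  merge into the worm-level table);
- the statistics layer: Tukey-fence outlier filtering, well aggregation,
  repeatability CV% combinatorics, SSMD, power analysis, constrained
  four-parameter-logistic EC\_F estimation with confidence intervals,
  extra-sum-of-squares curve comparison and endpoint-sensitivity ranking.

## The core model

Concentration-response curves are fitted per endpoint to well means with a
four-parameter logistic in linear concentration,

```
y(c) = Bottom + (Top − Bottom) / (1 + (c / EC50)^h),    h > 0,
```

so solvent controls (c = 0) sit at Top exactly.  The lower asymptote is
constrained to the minimum biologically possible value — 0 embryos for
reproductive endpoints; L1-larva dimensions for developmental endpoints
(length 150 µm, area 1,500 µm², volume 11,775 µm³ from the cylinder model
π(A/2L)²L with π = 3.14).  Effect concentrations follow as

```
EC_F = EC50 · (F / (100 − F))^(1/h),
```

with 95% Wald intervals on the log scale.  Assay quality and design use
CV% = 100·SD/mean over all C(n, k) replicate-well combinations, the
strictly standardized mean difference SSMD = (µ_c − µ_t)/√(σ_c² + σ_t²),
and one-sample one-tailed t-test power at n = 3 via the noncentral t
distribution.  Details and assumptions: [docs/methods.md](docs/methods.md).

## Worked example

```sh
python examples/render_and_measure.py
```

renders a gravid adult into a `D1` trapping channel and runs the
measurement chain:

```
rendered stack: (18, 3220, 269) (z, y, x) at 0.425 um/px, 6.0 um z-step
best focus: z = 8 (truth 8)
classification: full
length:  1251.7 um   (truth  1250.0, +0.13%)
area:     37789 um2  (truth   37859)
volume:   3174701 um3 (truth   3180141, -0.17%)
mask Dice vs truth: 0.999
embryos in truth: 2 early + 1 late = 3 total
```

The recovered focus plane, classification and body endpoints agree with the
generator's analytic ground truth to a fraction of a percent.  Other
examples: `chip_geometry.py` (taper profiles and the 2,184 / 12,984
image-count accounting), `plate_repeatability.py` (combo-CV%, minimum
detectable effect at 80% power, SSMD vs a degraded population),
`dose_response.py` (EC10/25/50 with CIs, sensitivity ranking, curve
comparison):

```
sensitivity ordering by EC10 (most sensitive first):
  late_embryos    EC10 = 0.414 uM [0.334-0.514]
  total_embryos   EC10 = 0.907 uM [0.774-1.063]
  body_length     EC10 = 2.184 uM [1.787-2.670]
```

A thin CLI wraps the same functions (`wormdart plan`, `simulate-chip`,
`simulate-plate`, `analyze-images`, `score`, `report`); the library API is
the primary interface.

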