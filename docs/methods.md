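# Methods

`wormdart` models a 24-well microfluidic chip whose wells each feed 40
tapered trapping channels (960 channels per device) that immobilise and
laterally orient single *C. elegans* for volumetric brightfield imaging, and
implements the analysis chain of the resulting DART (developmental and
reproductive toxicity) assay: six endpoints per worm — body length, area and
volume, plus early-, late- and total in-utero embryo counts — aggregated per
well, filtered, and fitted with constrained concentration-response curves.

## Chip and acquisition model

Channel cross-sections taper piecewise-linearly between control points.  The
shipped `D1` design runs from 98 x 102 um at the entrance to 24 x 40 um at
the exit over 3 mm (a single linear segment between the two known
dimensions; the physical taper is only described as gradual).  The `L4`
design narrows further to 10 x 17 um; its intermediate control point
(24 x 40 um at 2.4 mm) is a configurable default, since only the entrance
and narrowest dimensions are fixed.  Channels sit at a 150 um pitch, so a
1.3 mm-wide field of view at the 10x / 0.4 NA objective (0.425 um/px) spans
8 channels and a 40-channel well needs 5 FOVs.

Acquisition plans count images as
`wells x (fiduciary_frames + FOVs x z_slices x volumes)`.  With 24 wells, 1
fiduciary frame per well, 5 FOVs, 18 z-slices at 6 um step, the
single-timepoint plan yields 2,184 images and the timelapse plan (1 static +
5 timelapse volumes) 12,984.  The number of volumes is an explicit plan
parameter rather than a constant, because the per-well decomposition of the
timelapse protocol is reconstructed from the printed totals.  Low-
magnification overview imaging is excluded from plan accounting.

## Synthetic data generator

No raw imaging data are publicly deposited, so the generator is a
first-class module producing ground-truthed stand-ins at three levels.

**Rendered channel stacks.** A worm is a tube of radius `r(s)` along an
arc-length-parameterised sinusoidal centerline; the radius profile is blunt
(constant mid-body, sinusoidal tapers over 12% of the length at each end,
tips at 25% of the mid-body radius).  The true volume is the quadrature of
`pi r(s)^2 ds` (well within 0.1% of any independent integration rule at the
grid used).  A trapped worm is rendered *squeezed*: the cross-section at
axial position `s` is drawn as an equivalent-area rectangle of height
`h(s)` (the local channel height) and half-width `a(s) = pi r(s)^2 / (2
h(s))`, emulating full dorsoventral contact with the channel ceiling and
floor.  This is precisely the deformation regime in which the downstream
volume estimator — mask area integrated against channel height — is exact,
which is what makes the fixtures usable as morphometric oracles.  Partial
contact near the head and tail of real worms, and bodies that fill the
channel width, are not emulated; a spec whose squeezed width (plus a 2 um
clearance) exceeds the local channel width raises a geometry error rather
than rendering an infeasible pose.  Passing morphometric-recovery tests on
these fixtures therefore demonstrates correctness of the measurement chain
under the model's assumptions, not segmentation robustness on real tissue
texture.

Defocus is modelled as Gaussian blur with sigma proportional to the slice
distance from the true focus plane (2 px per slice by default) plus additive
Gaussian noise (2% of background); this gives the monotone sharpness profile
the autofocus operator requires without modelling the real optical PSF.
Embryos are ~50 x 30 um ellipses inside the body: early-stage embryos render
as granular-textured ellipses, late-stage ones contain a dark curled-larva
spiral, mirroring the morphological cue (2-fold elongation) scorers use.

**Well-plate phenotype tables.** Worm-level endpoints are sampled
hierarchically: a lognormal biological-replicate effect x a lognormal well
effect x worm-level noise, all CV-parameterised and strictly positive.
Baseline means are a healthy day-1 adult population — length 1,522 um, area
75.9e3 um2, volume 2.96e6 um3, 30.7 early / 14.0 late / 44.7 total embryos.
Worm-level spreads (length SD 60 um, area SD 5.5e3 um2, volume SD 0.3e6 um3,
embryo-count CV 18%) and the replicate/well CVs (4% / 1.5%) are stated
choices of plausible magnitude: published summaries report well-level SEMs
and replicate CVs, not worm-level distributions, so these defaults are
calibrated to produce inter-replicate well-mean CVs of a few percent, the
regime a well-run plate assay occupies.  Embryo totals are rounded
lognormal draws split early/late by a Beta-distributed fraction (kappa =
60) centred on the baseline early share; `total = early + late` holds by
construction.  A single shared replicate-effect CV across endpoint families
is a simplification — real endpoints show endpoint-specific repeatability.

**Concentration-response draws.** Well values are `4PL(c) x (1 + eps)` with
`eps ~ N(0, cv)`; the well-level 5% CV used in recovery tests matches the
repeatability the plate simulations produce.

All generators are pure functions of (config, seed).

## Image analysis

*Autofocus*: the best-focus slice maximises the variance of the 4-neighbour
discrete Laplacian, ties broken to the lowest index; an all-constant stack
is a "no focus signal" error.  *Fiduciary detection*: normalised
cross-correlation against the cross-shaped marker template with a score
threshold (default 0.5).  *Classification*: a channel is `none` when no
worm-like component exists (components are screened by mean width, which
rejects the thin channel-wall lines), `partial` when the largest component
reaches within 20 px of an axial crop boundary, `full` otherwise.  The
margin is configurable; the underlying full/partial criterion is not
quantified in published descriptions.

*Segmentation* is classical, behind a pluggable composite interface: the
per-pixel **minimum** across 5 slices centred on the best focus (a dark
worm on a bright field darkens where any slice is dark), background
normalisation by the median, relative threshold 0.72, morphological
closing, worm-like largest component, hole filling.  The deep-learning
segmenters used in production imaging systems are deliberately out of
scope; accuracy targets here (Dice >= 0.90 on fixtures) are set for this
classical default.

*Morphometrics*: area is the mask pixel count x pixel area.  Volume sums
`pixel_area x h(s)` over mask pixels, with `s` the pixel-centre axial
position; this equals the brute-force per-pixel oracle to machine
precision by construction.  Length is the longest geodesic path through the
spur-pruned skeleton (branches shorter than 5% of the skeleton are
removed), measured as a *smoothed polyline* (moving-average window ~9 px)
rather than a raw 8-connected chain — raw chains systematically
overestimate oblique curves by up to ~8% — plus the distance-transform
value at the two path endpoints.  The tip correction is required for
correctness, not cosmetics: the skeleton of a blunt tube ends about one
local half-width short of each end, so a bare geodesic underestimates a
1000-px-long rectangle by ~5%.

*Motility*: worm-scale dark blobs are matched frame-to-frame by nearest
centroid; a worm counts as moving when any displacement reaches the
threshold (default 2 px at overview magnification).  This supports
plate-level range finding where spontaneous movement is the viability
criterion.

## Embryo scoring

Embryo counting is annotation-driven (a CSV schema with one marker per
embryo, staged early/late at the 2-fold threshold) rather than automated:
the assay's reference datasets were scored manually by trained, blinded
users, and fidelity to that procedure means validating and aggregating
annotations, with automated detection left as a future plug-in.  Validation
collects all line-numbered errors (unknown stage vocabulary, missing keys,
out-of-range coordinates) before rejecting a file; exact duplicate markers
are deduplicated with a warning, while the same position marked with two
different stages is an error (v1 supports one scorer per worm).  Worms
flagged unscorable (typically intestinal obstruction of the uterus) carry
no counts downstream but propagate their reason into the merge audit.

The merge into the worm-level table keeps only `full`-classified worms with
a valid mask and scored embryos; every dropped row is attributed
(partial/none, segmentation failure, unscorable, unscored) so that input
rows reconcile exactly with output rows plus drops.

## Statistics

*Outlier filtering.* Tukey fences at `Q1 - 1.5 IQR, Q3 + 1.5 IQR`
(linear-interpolation quartiles, inclusive bounds, single pass) applied
per well to body volume and total embryo count, excluding a worm when
either endpoint falls outside (OR rule) — the contamination mode is debris
such as shed cuticle and egg clumps, which distorts exactly these
endpoints.  The grouping scope (per well) is configurable because the
published procedure does not state it.  Groups under 4 worms pass through
unfiltered with a warning.

*Repeatability.* For each well position present in `n >= k` replicates, the
CV% (100 x sample SD / mean) of the k corresponding well means is computed
for every one of the C(n, k) replicate subsets — 10 combinations per
position for 3-of-5 — and pooled across a condition's positions as mean
+/- SEM; per-position lists are retained because the published pooling is
ambiguous.  The raw k = 3 CV is reported without small-sample debiasing,
matching standard practice; note `E[CV] ~ c4(3) x true CV ~ 0.886 x true
CV`, which the round-trip tests account for.

*SSMD.* Method-of-moments with sample SDs,
`(mean_ctrl - mean_trt) / sqrt(SD_ctrl^2 + SD_trt^2)`, signed so toxic
reductions are positive; >= 3 labels excellent and 2-3 good separation.

*Power.* One-sample, one-tailed t test power via the noncentral t
distribution, noncentrality `sqrt(n) x effect x mean / SD`, default n = 3
and alpha = 0.05 over a 2.5-50% effect grid; the minimum detectable effect
at 80% power is linearly interpolated.  Verified against a 1e5-replicate
simulation oracle to < 0.005 absolute.

*4PL fitting.* `y(c) = Bottom + (Top - Bottom) / (1 + (c/EC50)^h)` in
linear concentration with h > 0, so c = 0 controls evaluate to Top exactly
— no pseudo-concentration placeholder for the solvent control.  The lower
asymptote is optionally fixed to the biological minimum: 0 for embryo
endpoints; for developmental endpoints, L1-larva dimensions (length 150 um,
area 1,500 um2) with volume 11,775 um3 derived from the cylinder model
`V = pi (A/2L)^2 L` at pi = 3.14.  Fitting is unweighted least squares on
well means (replicate wells enter as separate points) over internal
parameters (Top[, Bottom], log EC50, log h), with deterministic multi-start
initialisation (log-spaced EC50 grid x Hill slopes {0.5, 1, 2, 4}; best SS
wins) and Levenberg-Marquardt refinement at tight tolerances.  A fitted
EC50 outside `[min positive c / 100, max c x 100]`, or a flat response, is
an unidentifiable-fit error rather than a number.

*EC_F and intervals.* `EC_F = EC50 (F/(100-F))^(1/h)`.  The 95% CI is an
asymptotic Wald interval on log EC_F via the delta method (gradient
`[1, -L/h]` in (log EC50, log h), `L = ln(F/(100-F))`), with a t quantile
at the residual degrees of freedom.  Commercial packages use profile-based
machinery; the asymptotic interval is the stated stand-in, and its observed
coverage on simulated data (10 concentrations x 3 replicates, 5% noise)
sits in the low-to-mid 90s.

*Curve comparison.* Extra-sum-of-squares F test: the shared model ties the
tested parameters (by default log EC50 and log h) across two datasets; `F =
((SS_sh - SS_sep)/(df_sh - df_sep)) / (SS_sep/df_sep)`.

*Endpoint ordering.* Responses are normalised to control = 100% and the
bottom constraint = 0%; endpoints sort by ascending EC10 with flags where
adjacent 95% CIs overlap (ordering not resolved).

*Formatting.* Stars follow ns >= 0.05, * < 0.05, ** < 0.01, *** < 0.001,
**** < 0.0001.

## Numerical and testing choices

- Quartiles: linear interpolation of order statistics (so
  `{1,2,3,4,100}` gives fences [-1, 7] exactly).
- ANOVA delegates to the classical between/within decomposition
  (`scipy.stats.f_oneway`); degenerate all-equal input returns F = 0, p = 1.
- 4PL evaluation works on the log scale with a clipped exponent to avoid
  overflow at extreme starts.
- Determinism: all generators consume a `numpy` `default_rng(seed)`;
  pipeline reruns under the same config and seed are byte-identical.
- Test problem sizes: the rendered fixture suite used by the test suite is
  50 stacks (38 full across both designs, 7 partial, 5 none); EC50 CI
  coverage uses 500 simulated fits; the power oracle uses 1e5 Monte-Carlo
  replicates per grid point; the repeatability round trip uses 200 seeds.
  The acceptance script uses smaller versions of the same computations
  (12 fixtures, 200 fits, 100 seeds) — sizes chosen to keep a full
  from-scratch rerun comfortably interactive on one CPU.

## Known limitations

- The squeezed-body rendering model and classical segmenter mean fixture
  accuracy does not transfer to claims about real brightfield images of
  worms with gut granules, intestinal texture, or partial channel contact.
- One replicate-effect per endpoint family (not per endpoint) understates
  the endpoint-specific repeatability structure seen in real plates.
- Wald (not profile) intervals on EC_F; for very steep or poorly sampled
  curves the asymptotic approximation degrades.
- Multiple scorers per worm and inter-scorer agreement statistics are out
  of scope (one scorer per worm; conflicting duplicates are errors).
- Embryo detection is annotation-driven; no automated detector ships.
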