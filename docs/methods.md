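# Methods

## QC model

A session is a set of DICOM slices of a cylindrical water phantom (water at
0 HU inside a PMMA shell, surrounded by air at −1000 HU). Six key
performance indicators (KPIs) summarize scanner state; each is influenced by
a known set of more fundamental QC parameters, so a stable KPI set implies
stability of the parameters underneath, and a deviating KPI narrows the
search for the cause. Tolerances are engineering action limits, not
hypothesis tests: no multiplicity correction is applied across KPIs or
slices, and a session fails if any evaluated KPI on any slice is out of
band.

Verdicts are three-valued. `pass`/`fail` describe the scanner; `invalid`
describes the measurement (phantom not detected or truncated, required
slice missing, positioning markers absent). Miscentering beyond tolerance is
a `fail` of the positioning KPI, but an undetectable phantom invalidates the
session because every other KPI would then be computed from wrong geometry.

## Phantom detection and ROI placement

Segmentation thresholds at −500 HU (midway between air and water, so global
calibration drifts of tens of HU cannot move the boundary materially); the
phantom is the largest 4-connected component, its center the pixel centroid,
its diameter the equivalent-circle diameter of the component area. Ties on
area are broken toward the isocenter. The detection is rejected (`invalid`)
if the component touches the image border or its area deviates more than
20 % from the configured geometry.

All percentage ROI rules use the *configured* water diameter D, not the
measured one: a noisy diameter estimate would otherwise change ROI sizes
between sessions, which is exactly the irreproducibility this automation
removes. The detected diameter serves only as the sanity check above.

ROI membership is by pixel-center distance; standard deviations are sample
SDs (ddof = 1), the CT-QC convention. The air ROI sits on the image-left
horizontal through the phantom center at 0.75 D from it (0.25 D outside the
water edge) — clear of the shell and of any table structure on the right.
This placement constrains the geometry: with the 25 cm reconstruction FOV of
the protocol, the ROI (radius 0.05 D) fits only for D ≲ 156 mm, one reason
the default phantom model uses a 150 mm water section (a common water-
phantom size; the true dimensions of any given vendor phantom go in the
configuration).

The homogeneity tile grid (32×32 px, fixed pixels, so the physical tile size
varies with FOV) is anchored at the detected phantom center rounded to the
nearest pixel, making the statistic invariant to phantom translation; a tile
qualifies only if all four corners lie inside the 0.85 D circle, so no tile
mixes in shell-contaminated pixels. Peripheral uniformity ROI centers use
the 0.15 D-from-edge rule (the operative automated definition; the
equivalent "1 cm from the edge" phrasing found in QC protocols is
reproduced by configuring `peripheral_edge_frac`).

## Positioning

X and Y offsets come from the detected center of the positioning-section
slice. For Z, the phantom model assumes two opposed 45° ramp markers on the
vertical axis at ±radius from the center: a longitudinal offset dz moves
their in-plane images apart symmetrically, so dz = (separation − 2·radius)/2.
This is a standard ramp construction (vendor marker layouts differ and are
configurable through `marker_layout`); the ramp dynamic range (default
±10 mm) bounds the decodable offset. Markers are segmented above the
midpoint between shell and marker HU; fewer than two detections raise a
distinct "markers undetected" error rather than an out-of-tolerance result.

## Noise model

The Brooks relation links noise variance to technique:
σ² ∝ e^(−μd) / (mA·s·kVp^n · b² · w · T), with the dose expanded as
D ∝ mA·s·kVp^n. The kilovoltage dependency factor n defaults to the
literature value 2.6 (it is a property of beam quality and detector
response, so it is configurable). The proportionality constant cancels in
every use here: the synthetic generator scales a base σ by the ratio of
predictions, and the diagnostic fits estimate their own amplitudes.

Two fits mirror what a physicist extracts from a Level-1 series:

* σ = a·kVp^b + c by nonlinear least squares (`scipy.optimize.curve_fit`,
  initialized at b₀ = −1.3, i.e. n = 2.6, c₀ = 0, a₀ from the first point),
  reporting n = −2b. Exactly constant σ makes a and b jointly
  unidentifiable (a → 0); that degenerate case collapses to the flat
  solution b = 0. The fitted power b is mapped to a *positive* n via
  n = −2b because σ ∝ kVp^(−n/2) — dimensional consistency with the Brooks
  form fixes the sign.
* σ = a/√mAs by linear least squares in 1/√mAs.

r² is 1 − SS_res/SS_tot about the mean of σ in both cases.

A caution that shapes the tests: on four kVp points the three-parameter
power fit is ill-conditioned, and with 2 % multiplicative noise on σ a
single fit has an interquartile spread of roughly ±0.6 in n. Individual
Level-1 fits are therefore diagnostic indications, not measurements; the
*median* over many repeats is unbiased and is what the recovery tests and
the acceptance script report.

## Level 0 / Level 1 orchestration

Level 0 is one positioning slice plus an 8-slice water scan at the standard
technique (120 kVp, 260 mA, 1 s, head SFOV, 25 cm FOV, 5 mm slices,
64×0.625 mm collimation, std kernel): 3 positioning results plus 5 image
KPIs on each of 8 slices. Level 1 is the positioning slice plus 15 water
scans (33 slices in total) in which exactly one factor varies per scan —
kVp (80/100/140), mA (100/180/600), rotation time (0.5/2 s),
collimation/thickness (64, 32, 16×0.625 at 5/2.5/1.25 mm), SFOV
(medium/body) and kernel (edge).

Every Level-1 group gets the full KPI computation, but pass/fail is
evaluated only for groups at the daily (Level-0) technique: the fixed HU
action limits are calibrated for σ ≈ 5 HU images, and at, say, 80 kVp with
8×0.625 collimation the noise is ~24 HU, where a 3 HU uniformity difference
arises by chance alone. The varied-technique values are recorded as
informational rows of the per-technique group table and feed the two fits
(kVp-varied groups into the power fit, mA/rotation-varied groups into the
mAs fit — six mAs points: 100, 130, 180, 260, 520, 600). Missing groups
degrade gracefully: a fit without enough points is omitted with a logged
warning.

Noise pass/fail additionally requires a stored base value for the exact
(scanner, technique) pair — the base value is set once at acceptance
testing and can only be overwritten with an explicit force flag. Protocol
conformance (same technique every day, the precondition for comparing σ to
its base value) is checked against the expected row table and reported
field-by-field, without blocking the analysis.

Persistence is deliberately plain: an append-only JSON-lines file per
scanner (one record per KPI value, UTC ISO-8601 timestamps) plus a JSON
baseline store — flat, diff-able, dependency-free — with CSV export for
trend analysis. Diagnostic hints attached to failures are a static
KPI → parameter map; root-cause inference is left to the physicist.

## Synthetic phantom generator

The generator emulates the study conditions, not a CT reconstruction. A
slice is built from area-fraction (one-pixel linear) partial-volume mixing
of air/shell/water disks, plus the configured degradations:

* global HU drift of the water value (calibration error) — water KPI;
* radial quadratic cupping −k·(r/R_w)² (beam hardening) — uniformity and
  homogeneity, which rise monotonically together in k;
* a narrow ring (box annulus of given radius, amplitude, width) — noise
  and homogeneity;
* a tile-aligned square defect — homogeneity, exactly equal to its
  amplitude in the noiseless case;
* in-plane offsets and a marker-encoded dz — positioning.

Noise is white Gaussian with SD = base_sigma × the Brooks ratio between the
slice's technique and a reference technique (default: the Level-0 water
row; base_sigma default 5 HU, a typical head-QA value). Pixels are rounded
to integer HU exactly as DICOM storage would hold them, so in-memory slices
are pixel-identical to a write/read round trip; the rounding adds 1/12 HU²
of variance (≤ 0.3 % on σ ≥ 3 HU), which the 3 % tolerances of the scaling
tests absorb. Not modelled: correlated reconstruction texture, scatter,
photon starvation, beam-hardening spectra beyond the single exponent n.
Passing tests therefore demonstrate correctness of the ROI rules,
statistics, scaling laws and decision logic — not robustness to
reconstruction-specific noise texture on clinical scanners.

All randomness flows from one integer seed through per-slice
`SeedSequence` spawns; identical configuration and seed give bit-identical
sessions, including the DICOM files (UIDs and dates derive from content and
a series tag, not from wall-clock or entropy).

## DICOM representation

Files are CT Image Storage objects, signed 16-bit, RescaleSlope 1 /
RescaleIntercept −1024 (representing integer HU in [−1024, 31743] exactly);
rescale is applied exactly once on read. Non-integer HU are refused at
write time rather than silently quantized. Technique tags: KVP,
XRayTubeCurrent, ExposureTime (ms → rotation time), SliceThickness,
Single/TotalCollimationWidth (→ "N×w" collimation text), FilterType (SFOV
label), ConvolutionKernel, ReconstructionDiameter, StationName,
SeriesDescription (scanned part: water/positioning). Slices sort by
SliceLocation, stably, independent of file names. Acquisition grouping
keys on the scanned part plus the full technique tuple — the part label is
required because the Level-1 positioning scan shares its technique with
one water scan.

## Problem sizes used in the validation suite

Synthetic images are 512×512 at 25 cm FOV (0.488 mm pixels), the
protocol's matrix. The acceptance properties use 20 slices for oracle
equivalence, 10 seeds for the √2 dose-ratio law, 100 simulations per true
exponent for kVp recovery, 50 seeds per degradation-detection rate, and a
5×3 offset grid for center recovery; the acceptance script fits 4 mAs
points once and 4 kVp points × 100 repeats. These sizes give comfortable
statistical margins for every asserted property while keeping the whole
suite near half a minute.

## Known limitations

* The marker scheme is a generic ramp surrogate; decoding a specific
  vendor's positioning section requires configuring (or extending)
  `marker_layout`.
* Fixed-pixel homogeneity tiles change physical size with FOV; comparisons
  across FOVs compare different physical scales.
* The air ROI placement assumes the phantom is small enough relative to
  the FOV (D ≲ 0.62 × FOV); larger phantoms need a configured placement.
* White-noise simulation understates the spatial correlation of real
  reconstruction noise, so homogeneity false-positive rates on clinical
  data may differ from the synthetic ones.
* A Level-0 failure is reported with a Level-1 recommendation; nothing
  blocks clinical use automatically.
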