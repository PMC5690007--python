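# ctqc — automated daily quality control of CT scanners

`ctqc` automates the routine quality control (QC) of a CT scanner from images
of the manufacturer's cylindrical water QA phantom. Instead of a physicist
manually placing regions of interest once a year, a technologist scans the
phantom daily; `ctqc` finds the phantom, places every ROI reproducibly,
computes six **key performance indicators (KPIs)**, judges them against
action limits, stores every value in a trend database, and — when something
drifts — points at the underlying scanner parameters that KPI depends on.

The package is aimed at medical physicists and imaging-QA engineers. It
reads standard DICOM CT series, and it ships a fully seeded synthetic
phantom generator so the whole pipeline can be exercised (and its detection
properties measured) without a scanner.

## The KPIs

All image KPIs are measured on slices of the homogeneous water section;
positioning uses a dedicated marker section. With phantom (water) diameter
*D*:

| KPI | definition | default tolerance |
|---|---|---|
| positioning X/Y/Z | phantom-center and marker-decoded offsets | ±2 mm |
| image noise σ | SD of HU in a centered ROI of diameter 0.40 *D* | ±5 % of base value |
| CT number of water | mean HU of a centered 0.10 *D* ROI | 0 ± 2 HU |
| CT number of air | mean HU of a 0.10 *D* ROI outside the phantom | −1000 ± 10 HU |
| uniformity | max \|peripheral − center\| ROI-mean difference (four 0.10 *D* ROIs at 3/6/9/12 o'clock, centers 0.15 *D* from the edge) | 3 HU |
| homogeneity | max − min of mean HU over contiguous 32×32-px tiles inside the 0.85 *D* circle | 5 HU |

The noise base value is defined once at acceptance testing and stored per
(scanner, technique). Noise behaviour is modelled with the Brooks relation

σ² ∝ e^(−μd) / (mA · s · kVp^n · b² · w · T),

with object attenuation e^(−μd), sampling distance *b*, collimation *w*,
slice thickness *T* and kilovoltage dependency factor *n* ≈ 2.6, so that any
dose change predicts σ_new/σ_old = √(D_old/D_new). A **Level 0** session
(1 positioning slice + 8 water slices) is the daily pass/fail test; a
**Level 1** session (33 slices, one technique factor varied per scan)
diagnoses a failure, including least-squares fits of σ = a·kVp^b + c
(recovering n = −2b) and σ = a/√mAs.

## Worked example

Simulate a nominal daily session, register the noise base value, analyze:

```bash
$ ctqc simulate --level 0 --scenario nominal --seed 7 --out scans/daily
wrote 9 DICOM files to scans/daily
$ ctqc baseline set --scanner CT1 \
    --technique water_120kVp_260mA_1s_5mm_64x0.625_head_std --value 5.0
baseline set: CT1/water_120kVp_260mA_1s_5mm_64x0.625_head_std = 5 HU
$ ctqc analyze scans/daily --level 0
verdict: pass (report: qc_reports/CT1_level0_20240102T070000.json)
```

The text report (excerpt):

```
CT QC report - scanner CT1 - Level 0
verdict: PASS

KPI              slice       value                      band  status
positioning_x       -1       0.001             [-2.00, 2.00]    pass
positioning_y       -1       0.000             [-2.00, 2.00]    pass
positioning_z       -1       0.034             [-2.00, 2.00]    pass
noise                0       5.001              [4.75, 5.25]    pass
water                0       0.016             [-2.00, 2.00]    pass
air                  0   -1000.226       [-1010.00, -990.00]    pass
uniformity           0       0.126              [0.00, 3.00]    pass
homogeneity          0       0.510              [0.00, 5.00]    pass
...
```

The phantom was found within 0.04 mm of the isocenter, the measured noise
(5.001 HU) sits on its 5 HU base value, water and air are at their nominal
CT numbers, and the spatial statistics are far below their action limits —
the scanner is cleared for clinical use. A miscalibrated scanner is caught
and explained instead:

```bash
$ ctqc simulate --level 0 --scenario drift --seed 8 --out scans/drifted
$ ctqc analyze scans/drifted --level 0   # exit code 1
verdict: fail (...)
```

```
Failing KPIs depend on (check these QC parameters):
  water: CT number of water, CT number of air, Calibration
note: KPI water out of tolerance on slice 0: value 3.086 outside [-2.000, 2.000]
...
note: Level 0 failed: a Level 1 diagnostic test is recommended.
```

The injected +3 HU calibration drift fails exactly the water KPI on every
slice (a constant shift moves no noise/uniformity/homogeneity value and
stays inside the ±10 HU air band), and the report hints at calibration as
the parameter to check. `ctqc trend --scanner CT1 --kpi water --out w.csv`
exports the accumulated per-slice history; `ctqc analyze --level 1` adds the
per-technique group table and both Brooks fits to the report.

## Layout

- `src/ctqc/dicom_io.py` — DICOM read/write, HU rescale, technique grouping
- `src/ctqc/phantom_geometry.py` — phantom detection, positioning, ROI placement
- `src/ctqc/kpi_core.py` — ROI statistics, the six KPIs, tolerance evaluation
- `src/ctqc/brooks_model.py` — noise prediction and the kVp/mAs fits
- `src/ctqc/qc_engine.py` — Level-0/1 sessions, protocol matching, stores, trends
- `src/ctqc/synthetic_phantom.py` — seeded synthetic sessions with ground truth
- `src/ctqc/cli.py`, `src/ctqc/config.py` — command line, reports, configuration

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
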