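# airwaymorph

Upper-airway CT morphometry pipeline: landmark-driven airway segmentation
and partitioning, the ten standard airway parameters, and between-scan
variation / repeatability statistics — exercised end-to-end on synthetic
airway phantoms with analytically known ground truth.

## What it does

* **phantom** — generates paired synthetic CT scans: a tubular air lumen
  (HU ≈ −1000) with a prescribed cross-sectional area / ellipse-ratio
  profile embedded in soft tissue (HU ≈ +40), plus anterior dead-space
  pockets (mouth, vallecula), disconnected air islands, landmarks on the
  geometry, and a paired-scan perturbation model (smooth area scaling,
  landmark jitter, axis bend). Every reported parameter is also computed
  analytically by quadrature (`analytic_truth`), independent of any
  voxelization.
* **frame** — Frankfort-Horizontal plane construction from porion/orbitale
  fiducials, derived midpoint landmark (MUE), volume/landmark reorientation,
  and least-squares rigid (Kabsch) superimposition of paired scans.
* **segmentation** — air thresholding (strict `HU < −400`), cropping to the
  PNS/BEP boundary planes with the anterior PNS cut, island removal
  (3D components that do not span both boundary slices), dead-space removal
  (seeded slice-descent), and exact partitioning into velopharynx /
  oropharynx / tongue-base / epiglottis slabs at the landmark heights.
* **morphometry** — V, L, SA (open), SA′ (closed), MCA and its height,
  LAT/AP at the MCA slice, meanCSA = V/L, LAT/AP ratio, uniformity =
  MCA/meanCSA, and sphericity = π^(1/3)·(6V)^(2/3)/SA′. Surfaces come from
  marching cubes on a Gaussian-smoothed mask (σ = 1 voxel); a voxel-face
  variant is available as a cross-check.
* **stats** — relative difference `(|a−b|/mean)·100%`, ICC (default
  ICC(2,1), two-way random / absolute agreement / single measurement, with
  ICC(1,1) and ICC(3,1) selectable), Bland-Altman limits of agreement, the
  smallest detectable difference `1.96·SD(T0−T1)`, and a 50-row
  (10 parameters × 5 regions) cohort report.
* **io_cli** — NIfTI/landmark-JSON/CSV/STL readers and writers and the
  `airwaymorph` command-line pipeline. DICOM series reading is available
  when the optional `pydicom` dependency is installed.

## CLI

```sh
# generate a paired-scan phantom cohort (volumes + landmarks + truths)
airwaymorph phantom --n 10 --seed 1 --out cohort/

# measure one scan
airwaymorph measure cohort/S01_T0.nii.gz cohort/S01_T0_landmarks.json \
    --subject-id S01 --timepoint T0 --out S01_T0_params.csv

# process one subject's T0/T1 pair
airwaymorph compare cohort/S01_T0.nii.gz cohort/S01_T0_landmarks.json \
    cohort/S01_T1.nii.gz cohort/S01_T1_landmarks.json --out S01_diffs.csv

# cohort tables (variation/ICC and Bland-Altman/SDD) from a long-format CSV
airwaymorph report measurements.csv --out-prefix cohort
```

The long-format measurement CSV has columns
`subject_id, timepoint, region, parameter, value[, unit]` with timepoints
`T0`/`T1`, regions `total, velopharynx, oropharynx, tongue_base,
epiglottis`, and parameters
`V, L, SA, MCA, LAT, AP, meanCSA, LAT/AP, uniformity, sphericity`.
Landmark JSON is `{name: [x, y, z]}` in mm with names
`PNS, TUV, TEP, BEP` (+ optional `MUE`) and FH fiducials `PO_L, PO_R, OR`.
The internal frame is right-handed: +x left, +y anterior, +z superior.

## Interpretive conventions

The manual workflow the pipeline reproduces leaves a few operations
underspecified; the implemented conventions are:

* air test is strict (`HU < threshold`; a voxel at exactly −400 HU is tissue);
* an "island" is a 26-connected component that does not span from the
  superior to the inferior boundary slice;
* "dead space" is removed by seeded slice-descent from the most posterior
  air voxel on the top slice — pockets reachable only via a re-ascending
  path are excluded;
* the anterior cut at PNS is the single plane y = y(PNS) over the whole slab;
* region intervals are half-open (closed at each region's inferior plane),
  making the four-region partition an exact voxel partition;
* ICC class boundaries 0.40 / 0.75 map to the lower class.
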