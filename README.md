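# aortaquant

Automated aortic quantification from binary vessel segmentations.

Given a 3D binary aorta mask (from any upstream segmentation tool), the
package:

1. detects vessel endpoint candidates (3D skeleton leaves, spur-pruned,
   anchored to the end faces) and keeps the first candidate plus the one
   farthest from it as inlet/outlet;
2. extracts a centerline as a least-cost path through the foreground,
   with step costs inversely weighted by the distance-to-background
   transform, then smooths, re-centers on the medial ridge, and
   resamples it to uniform arc-length steps;
3. straightens the volume with a curved planar reformation using
   rotation-minimizing frames (1 mm isotropic, arc length on the third
   axis);
4. measures per-slice maximal (Feret) diameter — convex hull + rotating
   calipers — and cross-sectional area, smooths the profiles with a
   Savitzky–Golay filter (window 11, order 2, solved from the normal
   equations), splits them into ascending / arch / descending segments
   at the two landmark branch origins, and flags dilation against
   clinical thresholds (40 / 35 / 30 mm, strict inequality);
5. provides validation tooling: segmentation overlap and surface
   metrics (Dice, IoU, HD95, ASSD), agreement statistics (Pearson with
   Fisher-z CI, ICC(2,1) with F-based CI, Bland–Altman), ROC/AUC with
   bootstrap CI and the Youden-optimal operating point, and OLS
   regression calibration of measurements.

Because no clinical data ship with the package, the `phantom` module
generates voxelized tubular phantoms (straight tubes, torus segments,
and a candy-cane thoracic-aorta stand-in) with exact analytic ground
truth — centerline, radius profile, landmarks, dilation labels — plus
paired "contrast" (1 mm slices, lumen only) and "non-contrast" (3 mm
slices, lumen + wall) acquisition arms. Every pipeline stage is
validated against these analytic truths.

## CLI

```sh
aortaquant phantom --spec spec.yaml --seed 1 --out phantom_dir/
aortaquant quantify --mask aorta.nii.gz --landmarks lm.json \
    --out report.json --profile profile.csv [--thresholds 40,35,30]
aortaquant eval-seg --ref gt.nii.gz --pred pred.nii.gz --out metrics.json
aortaquant agree --table pairs.csv --cols gt,ai --out agree.json
aortaquant roc --table scores.csv --score-col max_diam \
    --label-col dilated --out roc.json
aortaquant paired-experiment --n 20 --seed 7 --out experiment_dir/
```

`lm.json` supplies the two landmark positions either as arc lengths
(`{"s_bct_mm": ..., "s_lsa_mm": ...}`) or as 3D points projected onto
the centerline (`{"bct_point_mm": [...], "lsa_point_mm": [...]}`).

`paired-experiment` generates a seeded synthetic cohort, quantifies
both acquisition arms per case, and writes `summary.json` (per-arm
agreement vs. truth, per-arm ROC, Bland–Altman between arms isolating
the wall bias) and `per_case.csv`.

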