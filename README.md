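# mitometry

Quantification of 3D/2D confocal imagery of neural progenitors:
mitotic-spindle geometry, cleavage-plane orientation, object-based and
Manders co-localization, fluorescence-distribution statistics, and
neural morphometry — together with synthetic phantom generators that
plant exact ground truth for validating every stage.

## The problem

In models of autosomal recessive primary microcephaly (MCPH),
neuroepithelial stem cells derived from patient iPSCs show subtle
defects in how they divide: the mitotic spindle tilts differently with
respect to the culture substrate, the cleavage plane of progenitors in
neural rosettes rotates from vertical (symmetric, proliferative) toward
horizontal (asymmetric, neurogenic) divisions, and spindle-pole
proteins such as WDR62 redistribute between the Golgi apparatus and the
spindle poles. These phenotypes are read out from multi-channel
confocal z-stacks by a handful of small geometric and intensity
measurements that are usually performed interactively. `mitometry`
implements those measurements as deterministic, scriptable, physically
calibrated operations, so the whole analysis can be validated against
planted ground truth and rerun bit-for-bit.

## Core measurements

With two spindle-pole (centrosome) positions in physical µm, `D` their
in-plane (xy) separation and `h` their axial (z) separation:

- **spindle angle** α = arctan(h / D), in [0°, 90°], the tilt of the
  spindle axis relative to the culture-dish plane;
- **inter-centrosomal distance** ICD = D / cos α = √(D² + h²), the 3D
  pole separation.

For a mitosis in a rosette section, with the tangent to the lumen
boundary at the point nearest the centrosome pair, `a` the perpendicular
distance of the farthest centrosome from the tangent and `b` its
distance to the intersection of the centrosome line with the tangent:

- **cleavage angle** θ = arccos(a / b); divisions with 45° ≤ θ ≤ 135°
  are classified vertical/symmetric, the rest horizontal/asymmetric,
  and per-genotype class counts are compared with a Pearson chi-square.

Co-localization is computed two ways: **object-based** (for each
segmented object in channel A, the fraction of its voxels within a
physical distance `d_max` of channel-B foreground, plus a per-object
call and the percentage of A objects called co-localized) and
**intensity-based** thresholded **Manders coefficients**
M1 = Σ A·1[A > t_A, B > t_B] / Σ A·1[A > t_A] (M2 symmetric).

Intensity and morphometry readouts include the ROI mean gray value and
skewness (population g1 = m3/m2^{3/2}), compartment enrichment
fractions (apical process / soma / basal process), mitotic index and
phase distributions from annotation tables, traced primary-cilium arc
length, TUBB3 density (TUBB3⁺ area per DAPI⁺ cell) and the area-based
average neurite length (TUBB3⁺ area minus perinuclear signal per
TUBB3⁺ cell).

## Worked example

```python
from mitometry import detect_spots, measure_spindles
from mitometry.synthetic import SpindleSimParams, make_spindle_stack

params = SpindleSimParams(n_cells=5, alpha_range_deg=(0, 60),
                          icd_range_um=(3, 8), snr=8.0, seed=11)
stack, truth = make_spindle_stack(params)
spots = detect_spots(stack, "centrosome", expected_sigma_um=0.3)
pairs, unmatched = measure_spindles(spots)
print(f"{len(pairs)} spindles measured ({len(unmatched)} unpaired spots)")
for p in sorted(pairs, key=lambda p: p.alpha_deg):
    print(f"  D = {p.d_um:5.2f} um   h = {p.h_um:5.2f} um   "
          f"alpha = {p.alpha_deg:6.2f} deg   ICD = {p.icd_um:5.2f} um")
```

prints

```
5 spindles measured (4 unpaired spots)
  D =  5.43 um   h =  0.53 um   alpha =   5.62 deg   ICD =  5.46 um
  D =  5.95 um   h =  0.66 um   alpha =   6.37 deg   ICD =  5.99 um
  D =  3.00 um   h =  2.38 um   alpha =  38.45 deg   ICD =  3.83 um
  D =  2.04 um   h =  3.00 um   alpha =  55.73 deg   ICD =  3.63 um
  D =  1.67 um   h =  2.72 um   alpha =  58.41 deg   ICD =  3.19 um
```

The five planted tilts were 4.23°, 7.79°, 37.31°, 55.69° and 56.90°, so
at a peak SNR of 8 each spindle is recovered to within ~1.5°; the four
unpaired detections are noise peaks that the mutual-nearest-neighbour
pairing correctly rejects. Every generator records its planted truth in
a `GroundTruthManifest` (here `truth`), so recovery can be scored
without touching the images.

A CLI mirrors the library (`mitometry simulate | segment | spindle |
cleavage | coloc | measure`); rerunning any stage with the same
configuration and seed reproduces its result tables byte for byte.

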