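# Default synthetic cohort: the congenitally-blind (CB) vs sighted-control
# (NC) study conditions this package emulates.
#
# Region order is rostro-caudal: anterior_third, anterior_midbody,
# posterior_midbody, isthmus, splenium (areas in mm^2, stereotaxic space).
# Splenium, posterior mid-body and isthmus carry the reported group means
# and SDs; the two anterior regions have no reported group difference, so
# both groups share one realistic mean/SD there.
# Bending angles are in degrees (vertex angle of the isosceles triangle on
# the bounding rectangle's base and height).
base_mm: 100.0
spacing_mm: 1.0
age_range: [19.0, 63.0]
seed: 0
groups:
  CB:
    n: 28
    n_male: 16
    region_means_mm2: [330.0, 95.0, 107.26, 79.4, 225.64]
    region_sds_mm2: [45.0, 15.0, 21.67, 16.66, 31.7]
    angle_mean_deg: 109.6
    angle_sd_deg: 4.9
  NC:
    n: 28
    n_male: 16
    region_means_mm2: [330.0, 95.0, 89.64, 64.16, 260.84]
    region_sds_mm2: [45.0, 15.0, 16.51, 10.31, 41.7]
    angle_mean_deg: 113.4
    angle_sd_deg: 5.7
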