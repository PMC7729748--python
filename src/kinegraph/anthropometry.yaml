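# Population anthropometric priors.
#
# axis_segment: mean and standard deviation (degrees) of the angle between
# the knee's rotation axis and the proximal direction of the flanking
# segment, from cadaver-study population measurements adapted to a
# right-pointing axis and proximal-pointing segment definition.
#
# lengths: mean/std and hard min/max windows (metres) for the distance
# between adjacent joint rotation centers, from population survey data
# (composite of male and female distributions).
axis_segment:
  left_femur:  {mu_deg: 96.0, sigma_deg: 2.4}
  left_tibia:  {mu_deg: 88.0, sigma_deg: 1.2}
  right_femur: {mu_deg: 84.0, sigma_deg: 2.4}
  right_tibia: {mu_deg: 92.0, sigma_deg: 1.2}
lengths:
  tibia: {mu: 0.411, sigma: 0.026, min: 0.344, max: 0.479}
  femur: {mu: 0.394, sigma: 0.030, min: 0.326, max: 0.480}
  pelvis: {mu: 0.187, sigma: 0.009, min: 0.0, max: 0.409}
discrepancy:
  femur: {sigma: 0.008}
  tibia: {sigma: 0.006}
window_sharpness: 100.0
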