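# Default cohort parameters for Bradypus variegatus suspensory walking.
# Peak-force and net-impulse distribution targets are the published pooled
# means +/- s.d. (%BW for peaks, %BWS for impulses); quantities the study did
# not print numerically (contact duration, fore-aft lobe timing, minor-lobe
# and medial-peak levels, speed) are package defaults documented in
# docs/methods.md.  Magnitude distributions are zero-truncated normals whose
# realized mean equals the stated mean.
body_mass_kg: {mean: 3.84, sd: 0.3}
n_animals: 5
rate_hz: 1200.0
speed_ms: {mean: 0.12, sd: 0.04}
duration_s: {mean: 3.0, sd: 0.5}
min_duration_s: 1.0
forelimb:
  n_contacts: 57
  vertical_peak: {mean: 68.6, sd: 10.6}
  net_impulse: {mean: 23.6, sd: 10.0}
  lateral_peak: {mean: 6.5, sd: 5.7}
  medial_peak: {mean: 4.0, sd: 3.0}
  minor_fore_aft_peak: {mean: 5.0, sd: 2.5}
  fore_aft_split_frac: 0.75   # propulsion early and long; modest braking before lift-off
  ml_split_frac: 0.4          # lateral purchase at touchdown, medial push later
hindlimb:
  n_contacts: 90
  vertical_peak: {mean: 82.0, sd: 13.2}
  net_impulse: {mean: -40.7, sd: 14.0}
  lateral_peak: {mean: 6.1, sd: 7.5}
  medial_peak: {mean: 9.0, sd: 5.0}
  minor_fore_aft_peak: {mean: 5.0, sd: 2.5}
  fore_aft_split_frac: 0.25   # brief early propulsion, then dominant braking
  ml_split_frac: 0.4
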