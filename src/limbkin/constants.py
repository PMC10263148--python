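"""Physical constants and package-wide defaults."""

#: standard gravity, m s^-2
GRAVITY = 9.80665

#: nominal force-platform sampling rate, Hz
DEFAULT_RATE_HZ = 1200.0

#: low-pass cutoff applied before peak/impulse extraction, Hz
DEFAULT_CUTOFF_HZ = 15.0

#: contact-detection threshold as a fraction of body weight
DEFAULT_CONTACT_THRESHOLD = 0.05

#: minimum persistence of a contact (samples at 1200 Hz -> 50 ms)
DEFAULT_MIN_CONTACT_SAMPLES = 60

#: tolerance (%BWS) inside which a net fore-aft impulse counts as neutral
DEFAULT_NEUTRAL_TOL = 1.0

#: heaviest calibration mass, kg (0.1-3.40 kg protocol)
MAX_CAL_MASS_KG = 3.40

#: sensor noise, N: 0.5% of the calibration full-scale load (3.40 kg -> 33.3 N)
DEFAULT_NOISE_SD_N = 0.005 * MAX_CAL_MASS_KG * GRAVITY
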