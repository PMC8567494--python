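# Default cortical-bone run. Every key is optional; omitted keys fall back
# to the built-in defaults (this file spells out the main ones).
#
# Wave speeds are design defaults for a healthy adult tibia, not measured
# constants: adjust medium.* per subject when modelling a specific dataset.

probe:
  element_count: 64
  pitch_mm: 0.3
  center_frequency_mhz: 2.5        # phased-array, bone window
  sampling_frequency_mhz: 10.0
  pulse_bandwidth: 0.6

medium:
  interface_skin_bone_depth_mm: 8.0
  interface_bone_marrow_depth_mm: 13.0
  c_tissue_m_s: 1570.0
  c_marrow_m_s: 1480.0
  bone_c0_m_s: 3300.0              # along the bone axis
  bone_a2: 0.06                    # weak-anisotropy coefficients
  bone_a4: 0.01

protocol:
  angle_min_deg: -8.0
  angle_max_deg: 8.0
  n_angles: 15
  frames: 400                      # 4 s at 100 Hz
  frame_rate_hz: 100.0
  # artery branch
  ensemble_size: 30
  prf_hz: 5000.0
  steer_angle_deg: 20.0

phantom:
  heart_rate_bpm: 60.0
  axial_peak_mm_s: -10.0           # toward the foot
  radial_peak_mm_s: -2.0           # centrifugal (marrow -> periosteum)
  blood_fraction_axial: 0.7
  drift_amplitude_mm: 0.4          # hand-held probe drift over the recording
  noise_snr_db: 30.0

filter:
  k: 12                            # SVD clutter threshold (axial / power Doppler)
  k_radial: 18                     # heavier threshold for the slow radial route
  k_artery: 3                      # per-ensemble threshold, artery branch

to:
  lambda0x_mm: 3.5                 # transverse-oscillation wavelength
  ensemble_frames: 6               # sliding autocorrelation window

hemodynamics:
  roi_lateral_extent_mm: 15.0      # 15 x 5 mm cortex ROI
  n_keep: 5                        # Fourier-series selection components
  band_low_hz: 0.3
  band_high_hz: 10.0

seed: 0
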