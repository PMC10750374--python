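# Demo pipeline configuration for `mstate-ri run --config demo_study.yaml`.
# All keys are optional; defaults reproduce this file's values unless noted.

seed: 1
n_per_group: 6          # subjects per group (TMNMT / Placebo)
n_channels: 60          # standard 10-10 montage subset
conditions: [pre, during, post]

# --- synthetic study generation ---------------------------------------
sim_fs_hz: 1000.0       # acquisition rate; resampled during preprocessing
length_s: 12.0          # per-recording duration (keep small for the demo)
mean_durations_ms: [60.0, 80.0, 100.0, 120.0]   # per-state dwell means
gfp_scale_uv: 10.0      # GFP envelope peak amplitude
noise_sd_uv: 2.5        # white sensor noise (SNR ~ 4 at envelope peaks)
oscillations:           # band-limited components: [low_hz, high_hz, rms_uv]
  - [8.0, 13.0, 3.0]

# injected group x condition effects (empty -> null study)
# keys are "GROUP:condition"; duration multipliers are keyed by state index
band_offsets_db: {}
duration_multipliers: {}
# example:
#   band_offsets_db: {"TMNMT:post": {alpha2: -3.0}}
#   duration_multipliers: {"TMNMT:post": {"1": 0.8}}

# --- preprocessing ----------------------------------------------------
target_fs_hz: 512.0
band: [0.5, 100.0]      # broadband FIR band-pass
notches: [50.0, 100.0]
epoch_length_s: 2.0
threshold_uv: 100.0     # epoch rejection: any |sample| above this
microstate_band: [2.0, 20.0]

# --- spectral ---------------------------------------------------------
welch_segment_s: 2.0
welch_overlap: 0.5

# --- microstate -------------------------------------------------------
k: 4
template_level: group   # back-fit with group(subgroup) templates
min_peak_separation_ms: 10.0
max_maps_per_subject: 400

# --- statistics -------------------------------------------------------
alpha: 0.05
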