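# Default run configuration (version 1).  Flat keys; analysis constants
# appear here exactly once and are loaded as the package-wide defaults.
config_version: 1
seed: 0

# cohort / QC
n_animals: 58
n_missing_lfp: 5
n_bad_probe: 9
n_no_units: 2
n_trials: 75

# electrode geometry and LFP preprocessing
electrode_pitch_um: 20.0
depth_span_um: 860.0
lfp_fs_hz: 1250.0
lowpass_cutoff_hz: 500.0
filter_order: 5
target_pitch_um: 40.0
baseline_subtract: true

# analysis grid and windows (ms relative to flash onset)
grid_m: 30
grid_k: 100
analysis_window_ms: [0.0, 100.0]
baseline_window_ms: [-250.0, 0.0]
peak_window_ms: [35.0, 60.0]
sustained_window_ms: [60.0, 100.0]

# delta-iCSD
icsd_context: experiment          # selects 800 µm; "model" selects 400 µm
icsd_radius_model_um: 400.0
icsd_radius_experiment_um: 800.0
conductivity_s_per_m: 0.3

# Wasserstein metric
depth_weight: 1.0                 # ground-metric anisotropy (depth vs time step)

# spiking analysis
rate_bin_ms: 1.0
rate_smooth_sigma_bins: 2
min_cells: 10
cutoff_cortex_ms: 0.4
cutoff_lgn_ms: 0.3

# synthetic variability
animal_latency_sd_ms: 3.0
animal_depth_sd_um: 40.0
animal_amplitude_cv: 0.2
trial_noise_sd_uv: 8.0
gamma_period_ms: 20.0
gamma_amplitude_uv: 4.0

# input pools
lgn_pool_units: 1263
lgn_pool_trials: 75
lgn_n_subsets: 10
lgn_target_units: 17400
sim_trials: 10
lm_pool_units: 1823

# synthetic spikes
spike_units_per_population: 30

# pipeline scale-down knobs (desk-scale substitutes for cluster jobs)
pipeline_csd_trials: 20           # trials simulated per animal for the CSD branch
pipeline_trial_wd_subset: 8       # trials entering per-animal inter-trial WDs
pipeline_spike_animals: 12        # animals carrying synthetic spike tables
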