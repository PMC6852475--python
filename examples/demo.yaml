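# Desk-scale demonstration run: 6+6 subjects, 12 regions, one planted
# theta-band envelope-correlation increase in the patient group.
# Full-protocol analyses use the defaults (512 Hz, 128 sensors, 90 ROIs,
# three 2-minute blocks, six bands) and --protocol-scale resampling.
out_dir: demo-run
seed: 1
n_per_group: 6
n_rois: 12
n_sensors: 32
fs: 64.0
duration: 96.0
n_blocks: 1
sensor_snr: 8.0
artifact_fraction: 0.01
bands:
  - [theta, 5, 7]
  - [alpha, 8, 13]
bandpass: [1.0, 30.0]
notch: null
measures: [AEC, iCoh]
n_perm: 100
n_boot: 200
n_resamples: 5
n_restarts: 5
k_candidates: [1, 2]
planted_effects:
  - kind: envelope_correlation
    band: theta
    rois: [0, 1]
    group_delta: 0.4
    baseline: 0.2
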