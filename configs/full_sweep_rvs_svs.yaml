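# Full-scale stimulation-parameter sweep: 11 replicate networks over the
# complete (K, T_s) grid for both sequence protocols, full 128 s CR-on and
# CR-off epochs.  This is a cluster-scale workload (11 x 77 cells x 256 s
# of simulated time per protocol); desk-scale validation uses reduced
# replicates and duration_scale (see README).
K_values: [0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50]
T_s_values: [64, 40, 29, 23, 19, 16, 14, 12, 11, 10, 9]
modes: [rvs, svs]
l: 100
replicates: 11
master_seed: 1000
duration_scale: 1.0
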