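# Demo study-shaped run: WT vs disease knock-in at two ages, with
# spike-gamma coupling degraded (kappa x 0.6) in the disease group at the
# older age only. Completes in well under a minute on one CPU.
design:
  groups:
    - [WT, 1m, 6]
    - [WT, 2m, 6]
    - [App, 1m, 6]
    - [App, 2m, 6]
  effects:
    - {genotype: App, age: 2m, kappa: 0.6}
  lfp:
    duration: 15.0
    sampling_rate: 5000.0
    carrier_freq: 30.0
  coupling:
    mean_rate: 15.0
    kappa: 4.0
  synaptic:
    duration: 15.0
    event_rate: 2.0
  master_seed: 42
alpha: 0.05
q_outlier: 0.01
control: WT
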