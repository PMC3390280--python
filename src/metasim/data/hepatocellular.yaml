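# Hepatocellular carcinoma scenario: MS engine, dissemination proportional to
# volume, m calibrated against the numerical colony-size reference.
scenario: hepatocellular
engine: MS
b: 7.3e10
mu: 0.00286
d_i: 0.6666666666666666
m: null            # calibrate against the reference visible-colony count
alpha_d: 1.0
T_env: 1.0
c_frac: 1.0e-4
grid_dt: 1.0
horizon: 2200.0
max_order: 2
visibility_threshold: 4.6e7
eval_times: [1110.0, 1310.0]
iks_gamma: 5.3e-8
iks_alpha: 0.663
seed: 1
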