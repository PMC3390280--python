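# GDR variant of the hepatocellular scenario: dissemination proportional to
# the tumour surface, matching the reference's fractal exponent 0.663.
scenario: hepatocellular_gdr
engine: GDR
b: 7.3e10
mu: 0.00286
d_i: 0.6666666666666666
m: null
alpha_d: 0.6666666666666666
epsilon: null      # fit so the GDR asymptote equals b
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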