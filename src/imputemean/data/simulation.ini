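# Monte Carlo study configurations.
#
# SIM-PAPER: the full-scale published design — a bivariate-normal finite
# population with the POP3 moments (sigma_y^2 = (Cy*Ybar)^2, etc.),
# N = 5000, n = 200, r = 160, m = 50000 replicates.  Expect minutes of
# runtime at this scale.
#
# SIM-DESK: a desk-scale variant of the same superpopulation for quick
# calibration checks.

[SIM-PAPER]
mu_y = 29.360
mu_x = 245.088
var_y = 2670.161
var_x = 354696.288
cov_yx = 29574.704
N = 5000
n = 200
r = 160
m = 50000
seed = 20240318

[SIM-DESK]
mu_y = 29.360
mu_x = 245.088
var_y = 2670.161
var_x = 354696.288
cov_yx = 29574.704
N = 1000
n = 100
r = 80
m = 5000
seed = 20240318
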