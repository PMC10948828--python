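# Moment parameters of the three benchmark natural populations
# (classical survey-sampling source datasets), with the sample/respondent
# sizes used throughout the theory reports.

[POP1]
N = 80
n = 25
r = 20
Ybar = 5182.638
Xbar = 285.125
Cy = 0.354
Cx = 0.949
rho = 0.914

[POP2]
N = 10
n = 5
r = 4
Ybar = 56.900
Xbar = 54.296
Cy = 0.184
Cx = 0.162
rho = 0.924

[POP3]
N = 284
n = 35
r = 25
Ybar = 29.360
Xbar = 245.088
Cy = 1.760
Cx = 2.430
rho = 0.961
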