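label,R2Ba,R2BggA,R2BggB,R2Bgb,R2Bgm,R2Bgmdel,R2Brfun,R2Brdeg,R2Brdel
R2Ba,,0.005 (0.009),0.009 (0.014),0.007 (0.013),0.007 (0.013),0.007 (0.014),0.007 (0.013),0.007 (n/c),0.011 (0.022)
R2BggA,0.084 (0.103),,0.009 (0.014),0.007 (0.013),0.007 (0.013),0.007 (0.014),0.007 (0.013),0.007 (n/c),0.011 (0.022)
R2BggB,0.555 (0.731),0.551 (0.731),,0.009 (0.014),0.009 (0.014),0.009 (0.015),0.009 (0.014),0.009 (n/c),0.013 (0.021)
R2Bgb,0.197 (0.227),0.193 (0.237),0.559 (0.732),,0.002 (0.005),0.002 (0.006),0.004 (0.007),0.005 (n/c),0.005 (0.013)
R2Bgm,0.199 (0.229),0.195 (0.235),0.559 (0.733),0.020 (0.031),,0.001 (0.002),0.004 (0.007),0.005 (n/c),0.002 (0.006)
R2Bgmdel,0.201 (0.235),0.196 (0.242),0.563 (0.737),0.023 (0.034),0.004 (0.004),,0.004 (0.008),0.006 (n/c),0.003 (0.007)
R2Brfun,0.193 (0.218),0.187 (0.222),0.557 (0.730),0.039 (0.053),0.045 (0.058),0.046 (0.060),,0.005 (n/c),0.006 (0.012)
R2Brdeg,0.200 (n/c),0.197 (n/c),0.560 (n/c),0.103 (n/c),0.106 (n/c),0.106 (n/c),0.094 (n/c),,0.009 (n/c)
R2Brdel,0.206 (0.285),0.222 (0.299),0.555 (0.756),0.047 (0.074),0.009 (0.016),0.010 (0.019),0.056 (0.072),0.124 (n/c),
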