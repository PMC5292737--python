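element_id,taxon,degenerate,fragment
R2Ba,atticus,0,0
R2BggA,grandii_grandii,0,0
R2BggB,grandii_grandii,0,0
R2Bgb,benazzii,0,0
R2Bgm,maretimi,0,0
R2Bgmdel,maretimi,0,0
R2Brfun,rossius,0,0
R2Brdeg,rossius,1,0
R2Brdel,rossius,0,1
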