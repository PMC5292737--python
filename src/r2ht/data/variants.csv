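element_id,kind,ref_start,ref_end,length_bp
R2Bgmdel,deletion,1035,1460,426
R2Brdel,deletion,1035,1460,426
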