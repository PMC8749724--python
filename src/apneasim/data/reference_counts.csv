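angle_deg,displacement_um,detected_no_ir,unusable_no_ir,detected_ir,unusable_ir
45,500,86,14,93,7
45,1000,91,9,97,3
45,1500,93,7,99,1
90,500,84,16,92,8
90,1000,90,10,95,5
90,1500,95,5,98,2
135,500,87,13,94,6
135,1000,91,9,97,3
135,1500,95,5,99,1
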