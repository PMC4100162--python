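component	R-AMC	D-AMC
dE_ele	-172.62	-106.88
dE_vdW	-33.5	-31.4
dG_PB	170.65	129.89
dG_np	-5.44	-5.46
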