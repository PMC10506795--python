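name	ttp_s	fwhm_s	peak_psc
hrf1	3.5	2.5	0.9
hrf2	4.0	3.0	1.3
hrf3	4.5	3.5	1.7
hrf4	5.0	4.0	2.1
hrf5	5.5	4.5	2.5
hrf6	6.0	5.0	2.9
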