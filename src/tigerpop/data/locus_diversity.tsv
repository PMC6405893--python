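locus	H_E_Russia	H_O_Russia	PIC_Russia	H_E_China	H_O_China	PIC_China
FCA32	0.47	0.43	0.39	0.26	0.14	0.23
FCA69	0.70	0.56	0.59	0.44	0.40	0.39
FCA77	0.63	0.67	0.54	0.54	0.67	0.44
FCA105	0.65	0.56	0.54	0.60	0.73	0.52
FCA44	0.50	0.56	0.40	0.68	0.80	0.61
FCA161	0.76	0.78	0.67	0.74	0.80	0.66
FCA176	0.60	0.57	0.46	0.65	0.83	0.54
FCA220	0.57	0.78	0.47	0.60	0.80	0.49
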