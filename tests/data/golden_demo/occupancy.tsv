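pair	kind	occupancy	mean_distance
WC W1-C19	WC	1.0000	3.0765
WC W2-C18	WC	1.0000	2.9585
WC W3-C17	WC	1.0000	2.9830
WC W4-C16	WC	1.0000	3.0306
WC W5-C15	WC	1.0000	3.0456
WC W6-C14	WC	1.0000	2.9603
WC W7-C13	WC	1.0000	2.9729
WC W8-C12	WC	1.0000	3.0240
WC W9-C11	WC	1.0000	3.1038
WC W10-C10	WC	1.0000	3.0064
WC W11-C9	WC	1.0000	3.0087
WC W12-C8	WC	1.0000	2.9999
WC W13-C7	WC	1.0000	2.9405
WC W14-C6	WC	1.0000	2.9745
WC W15-C5	WC	1.0000	2.9786
WC W16-C4	WC	1.0000	2.9543
WC W17-C3	WC	1.0000	2.9196
WC C2-W18	WC	1.0000	2.9408
WC C1-W19	WC	1.0000	3.0137
HG W3-T1 (C+*G)	HG	1.0000	3.0079
HG W4-T2 (C+*G)	HG	1.0000	2.9342
HG W5-T3 (T*A)	HG	1.0000	2.9384
HG W6-T4 (T*A)	HG	0.0000	5.8864
HG W7-T5 (T*A)	HG	1.0000	2.9405
HG W8-T6 (T*A)	HG	1.0000	2.9672
HG W9-T7 (C+*G)	HG	1.0000	2.9535
HG W10-T8 (T*A)	HG	1.0000	2.9523
HG W11-T9 (T*A)	HG	1.0000	2.9144
HG W12-T10 (T*A)	HG	1.0000	2.8492
HG W13-T11 (T*A)	HG	1.0000	2.9133
HG W14-T12 (T*A)	HG	1.0000	2.9091
HG W15-T13 (T*A)	HG	1.0000	2.8840
HG W16-T14 (C+*G)	HG	1.0000	2.9265
HG W17-T15 (T*A)	HG	1.0000	3.0108
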