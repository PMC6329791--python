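motif	mod_type
GmANTC	m6A
TTAmA	m6A
GmCWGC	m4C
GmAANNNNTTC	m6A
GmATC	m6A
AGmCT	m4C
AmCGGC	m4C
GGWmCC	m5C
ACGmANNNNNNGRTC	m6A
GCAmAGG	m6A
GmAYNNNNNRTC	m6A
GmATGNNNNNNTAC	m6A
CGCmAG	m6A
GGmCC	m4C
GTmCGAC	m5C
CTmANNNNNNRTTC	m6A
GRGGAmAG	m6A
CmCWGG	m5C
GGTGmA	m6A
TCGmA	m6A
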