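# Enzyme Commission number -> pathway label
# BM butanoate metabolism, CAC citric acid cycle, GG glycolysis/gluconeogenesis,
# PPP pentose phosphate pathway, PM propanoate metabolism, NM nitrogen metabolism
1.1.1.1	GG
1.2.1.12	GG
1.6.5.3	NM
1.9.3.1	NM
2.3.1.9	BM
2.3.1.9	PM
2.7.1.11	GG
2.7.1.11	PPP
2.7.1.2	GG
2.7.1.63	GG
2.7.2.3	GG
4.2.1.11	GG
4.2.1.17	BM
4.2.1.17	PM
5.4.2.1	GG
6.3.5.4	NM
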