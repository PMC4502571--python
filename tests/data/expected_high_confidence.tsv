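orf_id	contig_id	donor	recipient	partner	ec
AU_c001_orf10	AU_c001	Alphaproteobacteria	Betaproteobacteria	Alphaproteobacteria	2.3.1.9
AU_c006_orf10	AU_c006	Gammaproteobacteria	Alphaproteobacteria	Gammaproteobacteria	4.2.1.17
AU_c007_orf10	AU_c007	Gammaproteobacteria	Betaproteobacteria	Gammaproteobacteria	2.7.1.11
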