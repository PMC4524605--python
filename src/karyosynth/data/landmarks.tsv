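species	kind	location	note
GHO	rDNA_18S28S	19	pericentromeric
GHO	rDNA_5S	8	proximal
GHO	ITS	14q	pericentromeric
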