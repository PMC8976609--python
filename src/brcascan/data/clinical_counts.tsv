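status	carriers	non_carriers
breast	285	2115
ovary	332	1365
breast_and_ovary	16	16
breast_or_ovary_plus_other	1	32
other_site	5	111
cancer_free	90	3551
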