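sample	sequence_type	raw_tag_count	clean_tag_count	clean_percent	mapped_tag_count	mapped_percent
HC-4	SE50	51420111	47942551	93.24	36387118	75.9
HSA	SE50	43734868	40682196	93.02	26272525	64.58
IC-1	SE50	48229628	43865674	90.95	21451106	48.9
IS-4	SE50	53763194	41563472	77.31	20568122	49.49
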