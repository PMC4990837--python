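# synthetic comparison file, shaped like a shotgun-proteomics export:
# a leading block of prose comment lines without any tab characters,
# then a tab-separated header whose first cell itself starts with '#',
# then the data rows.
# sample A: cytosolic fraction, GFP control
# sample B: RNA-binding protein pull-down
# abundance columns are APEX estimates from spectral counts
#PROTEIN ID	APEX 1	APEX 2
ENSP00000269305	12.5	3.1
P04637	0.8	1.9
ENST00000269305.2	5.0	5.0
7157	44.1	10.2
Q9Y6K9	2.25	9.0
ENSP00000344548	0.02	0.5
P38398	18.0	4.5
55294	1.1	1.05
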