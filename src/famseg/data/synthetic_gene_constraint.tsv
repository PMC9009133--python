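# Synthetic gene-level missense constraint table (observed/expected ratios).
# These values are illustrative stand-ins in the style of population-database
# gene constraint metrics; they are NOT real gnomAD values.
AMOTL1	0.82
VAV3	0.74
CDK5RAP3	0.61
ADGRE5	0.93
GLI1	0.71
PLXNB2	0.66
MUC4	1.54
TTN	1.31
OBSCN	1.42
HLA-DRB1	1.63
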