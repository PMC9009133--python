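#gene	bmd_gwas	disease	ko_phenotype	function_note
AMOTL1	N	N	N	Motin-family protein; attenuates Wnt/beta-catenin signaling
VAV3	N	N	Knockout mouse shows dense bones with impaired osteoclast differentiation and function	Rho-family guanine-nucleotide exchange factor organizing the osteoclast cytoskeleton
CDK5RAP3	Y	N	N	Tumor suppressor modulating NF-kB and beta-catenin nuclear localization via GSK3
ADGRE5	N	N	Knockout mouse shows increased trabecular bone volume with decreased osteoclast number and function	Adhesion GPCR (CD97) expressed in osteoclasts; positive regulator of osteoclast differentiation
GLI1	N	PA	N	Hedgehog-pathway transcription factor; hedgehog signaling drives osteoblast differentiation
PLXNB2	Y	N	N	Semaphorin 4D receptor promoting osteogenic differentiation through RhoA signaling
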