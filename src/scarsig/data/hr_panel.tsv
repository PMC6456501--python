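gene	source
ATM	biomarker-set
BRCA1	biomarker-set
BRCA2	biomarker-set
CDK12	biomarker-set
CHEK2	biomarker-set
FANCA	biomarker-set
HDAC2	biomarker-set
MLH3	biomarker-set
MRE11A	biomarker-set
NBN	biomarker-set
PALB2	biomarker-set
RAD51	biomarker-set
ATR	additional
BAP1	additional
BARD1	additional
BRIP1	additional
CHEK1	additional
FANCG	additional
RAD51B	additional
RAD51C	additional
RAD51D	additional
RPA1	additional
XRCC2	additional
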