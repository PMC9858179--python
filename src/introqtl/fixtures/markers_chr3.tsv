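marker	chrom	pos_bp
CMPSNP556	chr3	20373958
A_21-C11	chr3	20816308
ECM208	chr3	24346383
mc296EST	chr3	24668302
CMPSNP8	chr3	24780842
CMCTN5	chr3	24926308
CMN22-85	chr3	24931945
CMPSNP374	chr3	25197968
ECM60c	chr3	26205074
AI_06-G01	chr3	26328662
AI_14-F04	chr3	26434021
ECM205	chr3	26788316
MC215	chr3	26801772
TJ10	chr3	27143907
ECM125	chr3	27145624
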