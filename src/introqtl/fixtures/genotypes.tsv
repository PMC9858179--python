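line	CMPSNP556	A_21-C11	ECM208	mc296EST	CMPSNP8	CMCTN5	CMN22-85	CMPSNP374	ECM60c	AI_06-G01	AI_14-F04	ECM205	MC215	TJ10	ECM125
PS	PS	PS	PS	PS	PS	PS	PS	PS	PS	PS	PS	PS	PS	PS	PS
SC3-5-7	SC	SC	SC	SC	SC	SC	SC	SC	PS	PS	PS	PS	PS	PS	PS
SC3-5-8	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	PS	PS
SC3-5-12	PS	PS	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC
SC3-5-13	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	PS	PS	PS	PS	PS
SC3-5-14	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	SC	PS	PS	PS	PS
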