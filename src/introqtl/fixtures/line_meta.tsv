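line	class	n_replicates	lenient
PS	NC	21	0
SC3-5-7	NC	5	0
SC3-5-8	LC_MC	7	0
SC3-5-12	LC_MC	7	0
SC3-5-13	LC_MC	9	0
SC3-5-14	LC_MC	9	0
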