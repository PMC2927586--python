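stage,count
primer_designed,627
entry_clone,469
sequence_confirmed,469
expression_clone,442
agro_clone,353
dipped,353
transgenic_positive,266
in_soil,239
gfp_positive,150
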