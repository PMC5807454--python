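# UK EQ-5D-3L time-trade-off value-set decrements (Dolan 1997 MVH model).
# index = 1 - constant (if any dimension > 1) - sum of level decrements
#           - n3 (if any dimension at level 3)
term,value
constant,0.081
mobility_2,0.069
mobility_3,0.314
selfcare_2,0.104
selfcare_3,0.214
usualact_2,0.036
usualact_3,0.094
pain_2,0.123
pain_3,0.386
anxiety_2,0.071
anxiety_3,0.236
n3,0.269
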