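consumer,reference,printed_delta_d13c,printed_delta_d15n
gammaridae,food_plate,5.2,0.32
shrimp,food_plate,4.8,3.14
gambusia,gammaridae,-0.5,3.34
mullet,gammaridae,-1.8,1.83
goby,gambusia,-0.9,2.3
carp,gammaridae,-1.7,3.09
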