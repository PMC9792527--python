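taxon,d13c,d13c_sd,d15n,d15n_sd
food_plate,-22.1,,4.28,
gammaridae,-16.9,1.9,4.6,0.49
shrimp,-17.3,1.2,7.42,2.11
gambusia,-17.4,0.5,7.94,3.8
mullet,-18.7,0.1,6.43,0.22
goby,-18.3,1.4,10.24,0.23
carp,-18.6,0.9,7.69,0.45
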