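cause	deaths
Neoplasm	638
Circulatory system	208
Respiratory system	82
Digestive	47
Nervous system	43
External	35
Other (infections, congenital, endocrine, mental)	69
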