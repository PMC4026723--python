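(chicken,(platypus,(opossum,((cow,(horse,dog)ferungulata)laurasiatheria,((mouse,rat)rodentia,(macaque,(orangutan,(chimpanzee,human)hominini)hominidae)catarrhini)euarchontoglires)boreoeutheria)theria)mammalia)amniota;
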