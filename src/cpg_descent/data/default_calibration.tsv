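ancestor	age_mya
amniota	324.5
mammalia	217.8
theria	190.0
boreoeutheria	92.0
euarchontoglires	83.3
catarrhini	25.4
hominidae	18.0
hominini	7.2
human	0.0
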