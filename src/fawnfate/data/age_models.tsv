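# Registered neonatal age-from-hoof-growth calibrations.
# age_days = intercept + slope * new_hoof_growth_mm
# columns: species, name, label, intercept (days), slope (days/mm)
white-tailed deer	HaugenSpeake	HS	0.66	2.20
white-tailed deer	Sams	S	-8.29	3.66
white-tailed deer	Brinkman	B	-5.73	3.14
white-tailed deer	Haskell	H	0.57	3.87
mule deer	Robinette	R	-6.30	2.55
mule deer	Haskell	H	5.29	2.54
pronghorn	TuckerGarner	TG	0.89	2.34
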