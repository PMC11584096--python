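mutation	cause	prediction	starred
p.I857S	hypocalcemia	gain-of-function	1
p.Y825F	hypocalcemia	gain-of-function	1
p.P393R	hypercalcemia	loss-of-function	1
p.C60G	hypercalcemia	loss-of-function	1
p.D99N	hypercalcemia	loss-of-function	1
p.T186N	hypocalcemia	loss-of-function	0
p.A840V	hypocalcemia	gain-of-function	1
p.S448P	hypercalcemia	loss-of-function	1
p.L696V	hypocalcemia	gain-of-function	1
p.D433Y	hypercalcemia	loss-of-function	1
p.S147L	hypercalcemia	loss-of-function	1
p.D398N	hypercalcemia	loss-of-function	1
p.K805R	hypercalcemia	gain-of-function	0
p.C60Y	hypercalcemia	loss-of-function	1
p.L606P	hypercalcemia	loss-of-function	1
p.H41R	hypercalcemia	gain-of-function	0
p.A110D	hypercalcemia	gain-of-function	0
p.I139T	hypocalcemia	gain-of-function	1
p.Q164R	hypercalcemia	loss-of-function	1
p.T699N	hypercalcemia	gain-of-function	0
p.R701G	hypercalcemia	loss-of-function	1
p.T808P	hypercalcemia	loss-of-function	1
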