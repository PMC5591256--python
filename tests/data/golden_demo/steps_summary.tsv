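	mean
twist	36.0211
roll	-0.0208
tilt	-0.0506
shift	0.0035
slide	0.0014
rise	3.3785
x_displacement	0.0048
inclination	-0.0329
helical_twist	36.1298
helical_rise	3.3694
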