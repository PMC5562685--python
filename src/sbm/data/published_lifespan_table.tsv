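network	selected_order	r2	beta_high	ci_low	ci_high	t	p
anterior dorsal attention network	1	0.246	-3.75E-04	-4.31E-04	-3.19E-04	-13.19	1.36E-34
language-related speech network	1	0.139	-3.87E-04	-4.69E-04	-3.05E-04	-9.29	3.77E-19
cerebellum network 1	1	0.025	-9.44E-05	-1.45E-04	-4.41E-05	-3.68	2.54E-04
cerebellum network 2	1	0.028	-1.07E-04	-1.61E-04	-5.36E-05	-3.93	9.80E-05
ventral default mode network	1	0.340	-4.97E-04	-5.56E-04	-4.38E-04	-16.57	4.66E-50
posterior dorsal attention network	1	0.096	-2.29E-04	-2.89E-04	-1.70E-04	-7.52	2.40E-13
caudate-related network	1	0.168	-3.14E-04	-3.73E-04	-2.54E-04	-10.37	4.35E-23
posterior default mode network	1	0.043	-1.46E-04	-2.04E-04	-8.71E-05	-4.88	1.41E-06
auditory network	1	0.306	-4.58E-04	-5.16E-04	-3.99E-04	-15.34	2.90E-44
thalamus-related network	1	0.113	-3.92E-04	-4.85E-04	-2.98E-04	-8.24	1.32E-15
cerebellum network 3	1	0.157	-2.89E-04	-3.45E-04	-2.32E-04	-9.96	1.56E-21
sensory-motor network	1	0.280	-4.96E-04	-5.64E-04	-4.29E-04	-14.41	5.44E-40
hippocampus-related network	1	0.479	-5.67E-04	-6.17E-04	-5.17E-04	-22.17	1.11E-77
temporal lobe-related network	2	0.039	-1.01E-05	-1.44E-05	-5.75E-06	-4.59	5.66E-06
cerebellum network 4	1	0.070	-2.09E-04	-2.73E-04	-1.44E-04	-6.36	4.47E-10
cerebellum network 5	1	0.118	-2.80E-04	-3.45E-04	-2.15E-04	-8.45	2.88E-16
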