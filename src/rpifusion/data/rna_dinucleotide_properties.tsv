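unit	Adenine content	GC content	Purine content	Keto content	Cytosine content	Thymine content	Guanine content	Tilt	Twist	Roll	Rise	Shift	Slide	Stacking energy	Entropy	Entropy 1	Enthalpy	Enthalpy 1	Free energy	Free energy 1	Hydrophilicity	Hydrophilicity 1
AA	1	0	1	0	0	0	0	-0.8	31	7.2	3.18	-0.08	-1.27	-5.37	-19	-18.4	-6.82	-6.6	-0.93	-0.9	0.023	0.04
AC	0.5	0.5	0.5	0	0.5	0	0	0.8	32	4.8	3.24	0.23	-1.43	-10.51	-29.5	-26.2	-11.4	-10.2	-2.24	-2.1	0.083	0.14
AG	0.5	0.5	1	0.5	0	0	0.5	0.5	30	8.5	3.3	-0.04	-1.5	-6.78	-27.1	-19.2	-10.48	-7.6	-2.08	-1.7	0.035	0.08
AU	0.5	0	0.5	0.5	0	0.5	0	1.1	33	7.1	3.24	0.07	-1.36	-6.57	-26.7	-15.5	-9.38	-5.7	-1.1	-0.9	0.09	0.14
CA	0.5	0.5	0.5	0	0.5	0	0	1	31	9.9	3.09	0.11	-1.46	-6.57	-26.9	-27.8	-10.44	-10.5	-2.11	-1.8	0.118	0.21
CC	0	1	0	0	1	0	0	0.3	32	8.7	3.32	-0.01	-1.78	-8.26	-32.7	-29.7	-13.39	-12.2	-3.26	-2.9	0.349	0.49
CG	0	1	0.5	0.5	0.5	0	0.5	-0.1	27	12.1	3.3	0.3	-1.89	-9.69	-26.7	-19.4	-10.64	-8	-2.36	-2	0.193	0.35
CU	0	0.5	0	0.5	0.5	0.5	0	0.5	30	8.5	3.3	-0.04	-1.5	-6.78	-27.1	-19.2	-10.48	-7.6	-2.08	-1.7	0.378	0.52
GA	0.5	0.5	1	0.5	0	0	0.5	1.3	35	9.4	3.38	0.07	-1.7	-9.81	-32.5	-35.5	-12.44	-13.3	-2.35	-2.3	0.048	0.1
GC	0	1	0.5	0.5	0.5	0	0.5	0	32	6.1	3.22	0.07	-1.39	-14.59	-36.9	-34.9	-14.88	-14.2	-3.42	-3.4	0.146	0.26
GG	0	1	1	1	0	0	1	0.3	32	8.7	3.32	-0.01	-1.78	-8.26	-32.7	-29.7	-13.39	-12.2	-3.26	-2.9	0.065	0.17
GU	0	0.5	0.5	1	0	0.5	0.5	0.8	32	4.8	3.24	0.23	-1.43	-10.51	-26.9	-26.2	-10.44	-10.2	-2.11	-2.1	0.16	0.27
UA	0.5	0	0.5	0.5	0	0.5	0	-0.2	30	10.7	3.26	-0.02	-1.45	-3.82	-20.5	-22.6	-7.69	-8.1	-1.33	-1.1	0.112	0.21
UC	0	0.5	0	0.5	0.5	0.5	0	1.3	35	9.4	3.38	0.07	-1.7	-9.81	-32.5	-35.5	-12.44	-13.3	-2.35	-2.3	0.359	0.48
UG	0	0.5	0.5	1	0	0.5	0.5	1	31	9.9	3.09	0.11	-1.46	-6.57	-29.5	-27.8	-11.4	-10.5	-2.24	-1.8	0.224	0.34
UU	0	0	0	1	0	1	0	-0.8	31	7.2	3.18	-0.08	-1.27	-5.37	-19	-18.4	-6.82	-6.6	-0.93	-0.9	0.389	0.44
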