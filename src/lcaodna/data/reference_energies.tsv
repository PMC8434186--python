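# Reference ionization and excitation energies (eV) for the packaged
# heterocycle benchmark set.  quantity: ionization | excitation.
# kind: experiment (gas-phase measurement compilations) or cc (equation-of-
# motion coupled-cluster literature values, aug-cc-pVDZ).  channel labels the
# transition character the value refers to; only channel=pi (first pi
# ionization) / pi_pistar (first pi->pi* band) rows enter the RMSPE.
molecule	quantity	channel	kind	value_ev	citation
adenine	ionization	pi	experiment	8.44	pes-compilation
guanine	ionization	pi	experiment	8.24	pes-compilation
purine_9h	ionization	pi	experiment	9.52	pes-compilation
thymine	ionization	pi	experiment	9.14	pes-compilation
cytosine	ionization	pi	experiment	8.94	pes-compilation
uracil	ionization	pi	experiment	9.50	pes-compilation
pyrazine_14_dioxide	ionization	pi	experiment	8.33	pes-compilation
pyrazine	ionization	pi	experiment	10.18	pes-compilation
pyrazine	ionization	n	experiment	9.63	pes-compilation
pyrimidine	ionization	pi	experiment	10.41	pes-compilation
pyrimidine	ionization	n	experiment	9.73	pes-compilation
pyridazine	ionization	pi	experiment	10.61	pes-compilation
pyridazine	ionization	n	experiment	9.31	pes-compilation
imidazole_1h	ionization	pi	experiment	8.96	pes-compilation
pyrazole_1h	ionization	pi	experiment	9.38	pes-compilation
benzimidazole_1h	ionization	pi	experiment	8.44	pes-compilation
indazole_1h	ionization	pi	experiment	8.35	pes-compilation
azaindole_7	ionization	pi	experiment	8.11	pes-compilation
adenine	excitation	pi_pistar	experiment	4.84	uv-compilation
aminopurine_2	excitation	pi_pistar	experiment	4.11	uv-compilation
guanine	excitation	pi_pistar	experiment	4.51	uv-compilation
purine_9h	excitation	pi_pistar	experiment	4.68	uv-compilation
purine_9h	excitation	n_pistar	experiment	4.28	uv-compilation
thymine	excitation	pi_pistar	experiment	4.69	uv-compilation
cytosine	excitation	pi_pistar	experiment	4.64	uv-compilation
uracil	excitation	pi_pistar	experiment	4.79	uv-compilation
pyrazine_14_dioxide	excitation	pi_pistar	experiment	4.05	uv-compilation
pyrazine	excitation	pi_pistar	experiment	4.79	uv-compilation
pyrazine	excitation	n_pistar	experiment	4.20	uv-compilation
pyrimidine	excitation	pi_pistar	experiment	5.13	uv-compilation
pyrimidine	excitation	n_pistar	experiment	4.35	uv-compilation
pyridazine	excitation	pi_pistar	experiment	5.00	uv-compilation
pyridazine	excitation	n_pistar	experiment	3.70	uv-compilation
imidazole_1h	excitation	pi_pistar	experiment	5.99	uv-compilation
pyrazole_1h	excitation	pi_pistar	experiment	5.90	uv-compilation
benzimidazole_1h	excitation	pi_pistar	experiment	4.47	uv-compilation
indazole_1h	excitation	pi_pistar	experiment	4.27	uv-compilation
azaindole_7	excitation	pi_pistar	experiment	4.28	uv-compilation
adenine	ionization	pi	cc	8.23	eom-cc
aminopurine_2	ionization	pi	cc	7.95	eom-cc
guanine	ionization	pi	cc	7.83	eom-cc
purine_9h	ionization	pi	cc	9.34	eom-cc
purine_7h	ionization	pi	cc	9.40	eom-cc
thymine	ionization	pi	cc	9.03	eom-cc
cytosine	ionization	pi	cc	8.67	eom-cc
uracil	ionization	pi	cc	9.44	eom-cc
pyrazine_14_dioxide	ionization	pi	cc	8.11	eom-cc
pyrazine	ionization	pi	cc	10.09	eom-cc
pyrimidine	ionization	pi	cc	10.44	eom-cc
pyridazine	ionization	pi	cc	10.59	eom-cc
imidazole_1h	ionization	pi	cc	8.90	eom-cc
pyrazole_1h	ionization	pi	cc	9.35	eom-cc
benzimidazole_1h	ionization	pi	cc	8.40	eom-cc
indazole_1h	ionization	pi	cc	8.26	eom-cc
indazole_2h	ionization	pi	cc	7.90	eom-cc
azaindole_7	ionization	pi	cc	8.17	eom-cc
adenine	excitation	pi_pistar	cc	5.04	eom-cc
aminopurine_2	excitation	pi_pistar	cc	4.27	eom-cc
guanine	excitation	pi_pistar	cc	4.85	eom-cc
purine_9h	excitation	pi_pistar	cc	4.92	eom-cc
purine_7h	excitation	pi_pistar	cc	4.79	eom-cc
thymine	excitation	pi_pistar	cc	5.17	eom-cc
cytosine	excitation	pi_pistar	cc	4.64	eom-cc
uracil	excitation	pi_pistar	cc	5.27	eom-cc
pyrazine_14_dioxide	excitation	pi_pistar	cc	3.30	eom-cc
pyrazine	excitation	pi_pistar	cc	4.88	eom-cc
pyrimidine	excitation	pi_pistar	cc	5.25	eom-cc
pyridazine	excitation	pi_pistar	cc	5.12	eom-cc
imidazole_1h	excitation	pi_pistar	cc	6.29	eom-cc
pyrazole_1h	excitation	pi_pistar	cc	6.25	eom-cc
benzimidazole_1h	excitation	pi_pistar	cc	4.67	eom-cc
indazole_1h	excitation	pi_pistar	cc	4.50	eom-cc
indazole_2h	excitation	pi_pistar	cc	4.54	eom-cc
azaindole_7	excitation	pi_pistar	cc	4.50	eom-cc
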