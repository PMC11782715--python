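# 1H spin-system catalog for common brain metabolites at physiological pH.
# Chemical shifts and scalar couplings follow the standard published proton
# tables (values rounded; some minor proton groups and long-range couplings
# are omitted or averaged so every coupled network stays small).
#
# Columns (tab separated):
#   name     metabolite identifier
#   groups   semicolon list of  shift_ppm:multiplicity  per proton group
#   j_hz     semicolon list of  i-j:J_hz  couplings between group indices
#            (1-based; "-" for none).  Couplings act between every proton
#            of group i and every proton of group j.
#   t2_s     mono-exponential decay constant of the simulated FID
#   rel_conc physiological concentration relative to NAA (used only by the
#            randomized sampler, not by the physics)
#
# name	groups	j_hz	t2_s	rel_conc
NAA	2.008:3;4.382:1;2.673:1;2.486:1	2-3:3.86;2-4:9.82;3-4:-15.59	0.12	1.00
NAAG	2.042:3	-	0.12	0.15
Cr	3.027:3;3.913:2	-	0.12	0.65
PCr	3.029:3;3.930:2	-	0.12	0.35
Cho	3.185:9;4.054:2;3.501:2	2-3:5.0	0.12	0.25
Glu	3.743:1;2.042:1;2.120:1;2.336:1;2.352:1	1-2:7.33;1-3:4.65;2-3:-14.85;2-4:6.41;2-5:8.41;3-4:8.48;3-5:6.88;4-5:-15.92	0.12	0.75
Gln	3.753:1;2.129:1;2.109:1;2.432:1;2.454:1	1-2:5.85;1-3:6.53;2-3:-14.45;2-4:9.17;2-5:6.35;3-4:6.35;3-5:9.25;4-5:-15.55	0.12	0.30
Ins	3.522:1;4.054:1;3.522:1;3.614:1;3.269:1;3.614:1	1-2:2.89;2-3:3.01;3-4:9.99;4-5:9.48;5-6:9.48;1-6:9.99	0.12	0.50
sIns	3.340:6	-	0.12	0.05
Lac	1.313:3;4.097:1	1-2:6.93	0.12	0.15
GABA	2.284:2;1.889:2;3.013:2	1-2:7.30;2-3:7.90	0.12	0.15
Tau	3.246:2;3.420:2	1-2:6.70	0.12	0.15
Gly	3.548:2	-	0.12	0.10
Asp	3.891:1;2.801:1;2.653:1	1-2:3.65;1-3:9.11;2-3:-17.43	0.12	0.20
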