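animal_id,stage,age_class,clone_status,genotype,sex,age_label,age_days,R,F,G,S,C,A,I
955,foetus,perinatal,AI,,F,GD267,267,R0,F2,G2,S0,C0,A1,I0
964,foetus,perinatal,AI,,M,GD267,267,R0,F0,G2,S0,C0,A1,I0
972,foetus,perinatal,AI,,M,GD266,266,R0,F0,G2,S0,C0,A1,I0
979,foetus,perinatal,AI,,F,GD266,266,R0,F0,G2,S0,C0,A3,I0
92,foetus,perinatal,clone,5538,F,GD263,263,R2,F3,G0,S0,C1,A0,I0
411,foetus,perinatal,clone,2251,F,GD268,268,R2,F3,G0,S1,C2,A1,I0
828,foetus,perinatal,clone,2251,F,GD263,263,R2,F3,G2,S0,C1,A2,I0
3302,foetus,perinatal,clone,5538,F,GD257,257,R2,F3,G0,S1,C2,A2,I0
3303,foetus,perinatal,clone,5538,F,GD273,273,R2,F2,G0,S1,C0,A2,I0
3304,foetus,perinatal,clone,5538,F,GD273,273,R2,F0,G0,S2,C2,A2,I0
1171,calf,perinatal,AI,,F,PD4,284,R1,F0,G0,S2,C0,A1,I0
1226,calf,perinatal,AI,,F,PD4,284,R0,F0,G2,S0,C0,A0,I0
3594,calf,perinatal,AI,,F,PD4,284,R0,F0,G2,S0,C0,A1,I0
40,calf,perinatal,clone,5538,F,GD279,279,R0,F0,G2,S0,C0,A0,I0
61,calf,perinatal,clone,5538,F,GD281,281,R0,F0,G2,S0,C0,A0,I0
76,calf,perinatal,clone,5538,F,PD2,282,,,,,,,
406,calf,perinatal,clone,2251,F,GD281,281,R1,F3,G2,S0,C2,A0,I0
2263,calf,perinatal,clone,5538,F,PD4,284,,,,,,,
2,adult,adult,AI,,F,10 years,3653,R0,F0,G0,S0,C0,A0,I1
29,adult,adult,AI,0029,F,10 years,3653,R1,F0,G0,S0,C0,A0,I0
229,adult,adult,AI,,F,8 years,2922,,,,,,,
428,adult,adult,AI,,F,6 years,2192,R0,F0,G0,S0,C0,A1,I0
449,adult,adult,AI,,F,6 years,2192,R0,F0,G0,S0,C0,A0,I1
460,adult,adult,AI,,F,6 years,2192,R1,F2,G0,S0,C0,A2,I1
578,adult,adult,AI,,F,5 years,1826,R0,F0,G0,S0,C0,A0,I1
2353,adult,adult,AI,,F,7 years,2557,,,,,,,
5538,adult,adult,AI,5538,F,15 years,5479,R1,F2,G0,S0,C0,A1,I0
139,adult,adult,clone,7711,F,11 years,4018,,,,,,,
248,adult,adult,clone,5538,F,6 years,2192,R0,F2,G0,S0,C0,A0,I2
437,adult,adult,clone,0029,F,6 years,2192,R0,F2,G0,S0,C0,A0,I1
439,adult,adult,clone,2251,F,4 years,1461,R0,F2,G0,S0,C0,A0,I0
447,adult,adult,clone,0029,F,5 years,1826,R0,F0,G0,S0,C0,A0,I0
468,adult,adult,clone,5538,F,5 years,1826,R0,F2,G0,S0,C0,A1,I2
474,adult,adult,clone,2251,F,8.5 years,3105,,,,,,,
477,adult,adult,clone,5538,F,3.5 years,1278,R0,F2,G0,S0,C0,A0,I1
512,adult,adult,clone,5538,F,3 years,1096,R0,F2,G2,S0,C0,A0,I1
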