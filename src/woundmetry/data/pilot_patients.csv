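patient_id,sex,age,height_cm,weight_kg
P01,F,64,173,67
P02,F,27,180,70
P03,M,52,186,90
P04,M,54,183,100
P05,M,50,182,90
P06,M,19,174,83
P07,M,28,178,108
P08,M,63,180,114
P09,M,53,190,100
P10,F,79,165,70
P11,M,37,180,110
P12,M,58,168,90
P13,F,60,165,106
P14,M,65,180,80
P15,M,42,190,110
P16,M,77,180,80
P17,M,20,180,90
P18,M,21,175,90
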