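patient_id,mechanism,degree,surgery_flag
P01,Scald,II and III,1
P02,Fire,IIa,0
P03,Fire,III,0
P04,Scald,IIa,0
P05,Fire,IIa,0
P06,Explosion,IIb,0
P07,Explosion,IIa,0
P08,Explosion,IIb,0
P09,Fire,I and IIb,0
P10,Scald,I-III,1
P11,Explosion,IIb and III,0
P12,Scald,IIb,1
P13,Scald,IIb,0
P14,Scald,IIa,1
P15,Scald,IIb,0
P16,Fire,III,1
P17,Explosion,I and IIa,0
P18,Explosion,I and IIa,0
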