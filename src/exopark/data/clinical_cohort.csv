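subject_id,group,age,sex,handedness,disease_duration,levodopa_dose,other_medications,other_dose_mg,updrs3_off,updrs3_on,moca
PD01,PD,48,M,right,0.5,600,None,0,21,12,26
PD02,PD,55,M,right,6,600,None,0,26,12,25
PD03,PD,71,M,left,5,800,Entacapone,400,54,26,21
PD04,PD,67,M,right,5,700,"Rasagiline, Pramipexole","1, 0.25",22,11,27
PD05,PD,70,M,right,15,700,Entacapone,400,34,38,24
PD06,PD,67,M,right,11,400,Amantadine,200,46,13,22
PD07,PD,55,M,right,3,550,None,0,30,24,30
PD08,PD,72,M,right,13,350,None,0,33,22,27
PD09,PD,57,M,left,4,600,None,0,12,7,27
PD10,PD,69,M,right,6,875,None,0,29,16,26
PD11,PD,72,M,right,8,450,Pramipexole,1,28,22,26
PD12,PD,70,F,right,5,650,Entacapone,200,28,10,28
PD13,PD,53,M,right,2,1100,None,0,48,29,25
PD14,PD,61,M,left,3,300,None,0,24,15,29
PD15,PD,73,M,right,3,600,Pramipexole,3,18,7,25
PD16,PD,75,M,right,8,500,Pramipexole,4.5,23,21,26
PD17,PD,69,F,right,5,600,Pramipexole,1,38,27,25
PD18,PD,72,M,right,5,1000,Pramipexole,3,33,17,20
PD19,PD,68,M,right,5,1050,Pramipexole,0.75,42,16,25
PD20,PD,75,M,right,3,950,None,0,8,5,27
PD21,PD,58,M,right,5,600,Trihexyphenidyl,3,20,5,24
PD22,PD,54,F,left,4,450,Propranolol,60,27,16,26
PD23,PD,75,F,right,8,600,None,0,37,22,25
PD24,PD,47,M,right,3,450,None,0,27,11,26
PD25,PD,64,M,right,6,1000,Rotigotine patch,4,35,6,21
PD26,PD,71,F,right,2,400,None,0,29,18,25
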