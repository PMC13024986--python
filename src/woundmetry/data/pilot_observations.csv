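patient_id,location,day,area_cm2
P01,RLL,1,329.19
P01,RLL,10,191.12
P01,RLL,15,98.42
P01,LLL,1,21.07
P01,LLL,10,2.59
P01,LLL,15,2.21
P02,RUL,1,320.17
P02,RUL,5,111.82
P02,LUL,1,172.49
P02,LUL,5,38.28
P03,LLL,1,160.25
P03,LLL,3,164.05
P03,LLL,8,111.25
P03,LLL,11,85.53
P03,RUL,1,91.24
P03,RUL,3,60.34
P03,RUL,8,30.79
P03,RUL,11,11.38
P03,LUL,1,373.12
P03,LUL,3,324.53
P03,LUL,8,182.50
P03,LUL,11,176.94
P04,Torso,1,173.13
P04,Torso,3,147.85
P04,RUL,1,116.73
P04,RUL,3,94.08
P04,LUL,1,408.24
P04,LUL,3,297.79
P04,LLL,1,7.27
P04,LLL,3,5.46
P05,LUL,1,149.07
P05,LUL,3,93.55
P05,RUL,1,163.94
P05,RUL,3,51.65
P06,LUL,1,920.52
P06,LUL,3,322.40
P06,LUL,11,126.43
P06,RUL,1,721.13
P06,RUL,3,260.27
P06,RUL,11,104.01
P07,LUL,1,191.17
P07,LUL,5,145.88
P07,LUL,11,116.70
P07,RUL,1,188.22
P07,RUL,5,142.61
P07,RUL,11,142.19
P08,LUL,1,192.58
P08,LUL,5,135.47
P09,Torso,1,1596.06
P09,Torso,11,802.85
P09,RUL,1,2137.98
P09,RUL,11,1295.94
P09,LUL,1,629.73
P09,LUL,11,460.65
P09,RLL,1,2058.89
P09,RLL,11,1124.86
P09,LLL,1,323.56
P09,LLL,11,107.74
P10,Torso,1,583.47
P10,Torso,12,290.63
P10,Torso,19,223.45
P10,RUL,1,329.03
P10,RUL,12,143.90
P10,RUL,19,161.51
P10,RLL,1,93.56
P10,RLL,12,33.10
P10,RLL,19,16.18
P10,LUL,1,86.39
P10,LUL,12,21.66
P10,LUL,19,30.30
P11,Torso,1,538.18
P11,Torso,8,509.93
P11,RUL,1,833.13
P11,RUL,8,322.65
P12,RLL,1,1502.51
P12,RLL,3,1175.52
P12,RLL,8,941.05
P12,RLL,16,507.83
P12,RLL,23,402.60
P12,LLL,1,356.35
P12,LLL,3,156.60
P12,LLL,8,119.09
P12,LLL,16,49.81
P12,LLL,23,47.77
P13,Torso,1,568.36
P13,Torso,4,439.99
P13,Torso,9,80.83
P13,Torso,11,50.93
P13,Torso,37,43.79
P13,LUL,1,903.87
P13,LUL,4,847.21
P13,LUL,9,722.26
P13,LUL,11,530.28
P13,LUL,37,485.35
P14,RUL,1,652.70
P14,RUL,3,473.96
P14,RUL,7,286.85
P14,RUL,11,241.41
P14,LUL,1,1186.65
P14,LUL,3,685.30
P14,LUL,7,436.58
P14,LUL,11,320.79
P15,LLL,1,30.84
P15,LLL,5,13.39
P16,RLL,1,127.05
P16,RLL,7,125.18
P16,RLL,22,103.45
P17,Torso,1,1153.70
P17,Torso,7,391.96
P17,Torso,10,351.63
P17,RUL,1,685.07
P17,RUL,7,426.92
P17,RUL,10,411.91
P17,RLL,1,988.16
P17,RLL,7,789.28
P17,RLL,10,133.24
P18,RLL,1,88.78
P18,RLL,7,70.03
P18,RLL,10,54.96
P18,RUL,1,295.18
P18,RUL,7,250.69
P18,RUL,10,92.72
P18,LUL,1,947.80
P18,LUL,7,869.02
P18,LUL,10,622.87
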