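patient_id,location,printed_delta_a_cm2,printed_percent_reduction,flag
P01,RLL,230.77,70.1,
P01,LLL,18.86,89.51,
P02,RUL,208.35,65.07,
P02,LUL,134.21,77.81,
P03,LLL,74.72,46.63,
P03,RUL,79.86,87.53,
P03,LUL,196.18,52.58,
P04,Torso,25.28,14.6,
P04,RUL,22.65,19.4,
P04,LUL,110.45,27.6,percent_inconsistent
P04,LLL,1.81,24.9,
P05,LUL,55.52,37.24,
P05,RUL,112.29,68.49,
P06,LUL,74.47,8.9,delta_a_inconsistent;percent_inconsistent
P06,RUL,617.12,85.58,
P07,LUL,57.11,29.66,delta_a_inconsistent;percent_inconsistent
P07,RUL,46.03,24.46,
P08,LUL,57.11,29.66,
P09,Torso,793.21,49.7,
P09,RUL,842.04,39.39,
P09,LUL,169.08,26.84,
P09,RLL,934.03,45.38,percent_rounding
P09,LLL,215.82,66.72,percent_rounding
P10,Torso,360.02,61.68,percent_rounding
P10,RUL,167.52,50.9,percent_rounding
P10,RLL,77.38,82.7,
P10,LUL,56.09,64.93,
P11,Torso,28.25,5.25,
P11,RUL,510.48,61.27,
P12,RLL,1099.91,73.2,
P12,LLL,308.58,86.59,
P13,Torso,524.57,92.3,
P13,LUL,418.52,46.3,
P14,RUL,411.29,63.01,
P14,LUL,865.86,72.97,
P15,LLL,17.45,56.58,
P16,RLL,23.6,18.58,
P17,Torso,802.07,69.52,
P17,RUL,273.16,39.87,
P17,RLL,854.92,86.52,
P18,RLL,33.82,38.09,
P18,RUL,202.46,68.59,
P18,LUL,324.93,34.28,
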