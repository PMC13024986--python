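patient_id,printed_bsa_m2,printed_tbsa_scan_pct,printed_delta_tbsa_pct,flag
P01,1.79,2,1.388,
P02,1.88,3,1.816,
P03,2.14,3,1.632,
P04,2.22,3,0.721,
P05,2.15,6,1.145,printed_bsa_inconsistent;printed_delta_tbsa_inconsistent
P06,1.97,4,3.119,printed_delta_tbsa_inconsistent
P07,2.49,2,0.536,printed_bsa_inconsistent
P08,2.32,1,0.246,
P09,2.28,30,12.941,
P10,1.77,6,3.732,
P11,2.28,6,2.357,
P12,1.99,9,7.055,
P13,2.11,8,4.464,
P14,1.99,9,6.397,
P15,2.37,1,0.073,
P16,1.99,1,0.118,
P17,2.98,14,9.196,printed_bsa_inconsistent
P18,2.05,6,2.729,
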