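patient_id,lesion_id,tissue_class,administration,dose_mg_kg,time_h,suv_peak
P1,L1,bone,first,,2,BLQ
P1,L1,bone,first,,48,2.49
P1,L1,bone,first,,119,3.12
P1,L1,bone,second,,49,2.30
P1,L1,bone,second,,117,2.90
P1,L2,bone,first,,2,4.19
P1,L2,bone,first,,48,4.55
P1,L2,bone,first,,119,2.60
P1,L2,bone,second,,49,4.80
P1,L2,bone,second,,117,3.51
P1,L3,soft-tissue,first,,2,6.47
P1,L3,soft-tissue,first,,48,5.42
P1,L3,soft-tissue,first,,119,3.14
P1,L3,soft-tissue,second,,49,4.59
P1,L3,soft-tissue,second,,117,3.53
P1,L4,soft-tissue,first,,2,2.26
P1,L4,soft-tissue,first,,48,4.53
P1,L4,soft-tissue,first,,119,3.60
P1,L4,soft-tissue,second,,49,4.87
P1,L4,soft-tissue,second,,117,3.10
P1,L5,bone,first,,2,4.32
P1,L5,bone,first,,48,5.64
P1,L5,bone,first,,119,3.88
P1,L5,bone,second,,49,6.90
P1,L5,bone,second,,117,5.95
P1,L6,bone,first,,2,3.36
P1,L6,bone,first,,48,3.23
P1,L6,bone,first,,119,2.89
P1,L6,bone,second,,49,3.36
P1,L6,bone,second,,117,2.96
P2,L1,lung,first,,2,2.22
P2,L1,lung,first,,46,1.87
P2,L1,lung,first,,115,1.57
P2,L1,lung,second,,44,1.71
P2,L1,lung,second,,118,1.57
P3,L1,lung,first,,2,BLQ
P3,L1,lung,first,,50,2.19
P3,L1,lung,first,,116,1.26
P3,L1,lung,second,,49,3.59
P3,L1,lung,second,,139,3.78
P3,L2,bone,first,,2,BLQ
P3,L2,bone,first,,50,3.92
P3,L2,bone,first,,116,4.83
P3,L2,bone,second,,49,2.85
P3,L2,bone,second,,139,3.13
P3,L3,bone,first,,2,BLQ
P3,L3,bone,first,,50,5.30
P3,L3,bone,first,,116,5.87
P3,L3,bone,second,,49,5.78
P3,L3,bone,second,,139,6.20
P3,L4,bone,first,,2,BLQ
P3,L4,bone,first,,50,5.45
P3,L4,bone,first,,116,6.12
P3,L4,bone,second,,49,5.49
P3,L4,bone,second,,139,4.87
P4,L1,soft-tissue,first,,2,NA
P4,L1,soft-tissue,first,,51,9.94
P4,L1,soft-tissue,first,,116,12.01
P4,L1,soft-tissue,second,,45,5.72
P4,L1,soft-tissue,second,,115,5.92
P5,L1,lymph-node,first,,2,NA
P5,L1,lymph-node,first,,42,3.69
P5,L1,lymph-node,first,,138,3.84
P5,L1,lymph-node,second,,40,3.11
P5,L1,lymph-node,second,,113,3.97
P5,L2,bone,first,,2,NA
P5,L2,bone,first,,42,15.66
P5,L2,bone,first,,138,15.26
P5,L2,bone,second,,40,6.58
P5,L2,bone,second,,113,11.23
P5,L3,lymph-node,first,,2,NA
P5,L3,lymph-node,first,,42,4.45
P5,L3,lymph-node,first,,138,4.34
P5,L3,lymph-node,second,,40,3.32
P5,L3,lymph-node,second,,113,3.95
P5,L4,lymph-node,first,,2,NA
P5,L4,lymph-node,first,,42,3.96
P5,L4,lymph-node,first,,138,4.06
P5,L4,lymph-node,second,,40,2.72
P5,L4,lymph-node,second,,113,2.92
P5,L5,lymph-node,first,,2,NA
P5,L5,lymph-node,first,,42,3.22
P5,L5,lymph-node,first,,138,2.64
P5,L5,lymph-node,second,,40,4.22
P5,L5,lymph-node,second,,113,3.41
P5,L6,lymph-node,first,,2,NA
P5,L6,lymph-node,first,,42,4.60
P5,L6,lymph-node,first,,138,5.38
P5,L6,lymph-node,second,,40,4.50
P5,L6,lymph-node,second,,113,5.71
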