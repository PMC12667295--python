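compound_id,cell_line,papp_ab,papp_ab_sd,papp_ba,papp_ba_sd,recovery_ab,recovery_ab_sd,recovery_ba,recovery_ba_sd,er
Phenacetin,MOCK,35.2,0.08,27.23,1.32,118,2.92,99.1,1.86,0.77
Phenacetin,MDR1,36.6,2.48,28.98,1.19,119,1.31,99.2,1.34,0.79
Caffeine,MOCK,34.0,1.22,34.10,1.49,121,2.48,101,2.25,1.00
Caffeine,MDR1,36.4,1.42,33.26,1.49,118,5.78,94.9,7.10,0.91
Atipamezole,MOCK,33.9,1.72,30.19,4.52,117,7.46,102,8.10,0.89
Atipamezole,MDR1,33.7,5.21,27.55,1.50,118,11.1,107,6.44,0.82
Nimodipine,MOCK,33.7,2.08,46.24,1.79,109,7.08,91.7,4.14,1.37
Nimodipine,MDR1,32.2,1.83,44.54,5.11,114,5.22,94.1,1.67,1.39
705,MOCK,32.1,1.05,30.40,1.91,119,2.55,100,4.32,0.95
705,MDR1,31.5,0.40,30.93,2.17,111,3.53,102,3.55,0.98
Antipyrine,MOCK,31.4,3.13,23.61,1.43,116,7.41,95.2,2.32,0.73
Antipyrine,MDR1,30.9,1.46,28.93,1.75,113,1.41,102,10.05,0.93
Lamotrigine,MOCK,32.8,2.04,25.31,1.32,119,6.58,102,2.31,0.77
Lamotrigine,MDR1,30.9,1.72,29.70,0.70,120,5.55,99.2,1.10,0.96
Dexmedetomidine,MOCK,30.8,0.61,35.19,2.56,111,2.72,99.9,5.22,1.14
Dexmedetomidine,MDR1,30.2,3.4,29.13,3.62,112,10.0,92.7,8.47,0.96
Midazolam,MOCK,24.7,0.41,31.55,5.10,99.6,1.73,97.4,3.76,1.32
Midazolam,MDR1,29.5,1.00,27.02,2.23,100,3.00,98.7,9.60,0.91
Diazepam,MOCK,34.1,1.24,42.90,1.42,118,3.87,88.3,4.96,1.26
Diazepam,MDR1,28.6,0.41,41.92,1.30,110,1.05,93.3,7.98,1.47
Lidocaine,MOCK,27.3,0.96,27.01,0.42,101,2.23,96.3,1.19,0.99
Lidocaine,MDR1,27.3,0.51,26.88,0.43,103,1.97,95.1,0.82,0.98
Bupropion,MOCK,27.3,2.88,23.78,0.67,102,4.17,93.8,4.05,0.87
Bupropion,MDR1,26.6,2.58,19.52,1.00,104,7.38,89.1,1.66,0.73
Tramadol,MOCK,27.3,0.20,23.26,1.43,113,3.59,99.1,3.48,0.85
Tramadol,MDR1,26.3,1.05,25.18,1.10,109,2.73,103,5.78,0.96
Omeprazole,MOCK,34.2,0.55,28.87,1.39,119,2.39,87.2,1.79,0.84
Omeprazole,MDR1,25.4,0.66,41.51,2.92,113,1.46,106,0.51,1.63
Metoprolol,MOCK,30.1,3.88,24.01,1.39,114,8.95,109,3.06,0.8
Metoprolol,MDR1,24.5,0.19,25.51,0.59,116,1.08,104,2.28,1.04
Tolbutamide,MOCK,18.7,1.12,17.23,1.64,97.3,2.82,105,2.47,0.92
Tolbutamide,MDR1,24.5,0.06,22.83,0.20,104,1.21,98.9,1.62,0.93
Tacrine,MOCK,30.9,1.76,27.23,2.27,114,3.02,104,9.23,0.88
Tacrine,MDR1,23.6,1.10,34.11,2.16,105,4.23,92.5,2.49,1.45
Modafinil,MOCK,20.2,0.98,15.62,0.22,106,2.03,99.3,0.63,0.78
Modafinil,MDR1,22.7,0.45,23.93,0.91,107,3.40,99.08,1.69,1.05
Diphenhydramine,MOCK,25.6,2.21,22.54,1.26,101,7.46,96.71,8.61,0.88
Diphenhydramine,MDR1,22.6,1.21,20.83,1.39,89.3,3.00,90.0,3.50,0.92
1111,MOCK,31.8,3.31,27.31,0.83,112,6.99,104,0.41,0.86
1111,MDR1,21.7,0.51,23.3,2.12,90.4,1.69,100,3.37,1.07
Melatonin,MOCK,22.4,0.51,20.6,0.92,105,2.95,98.4,2.97,0.92
Melatonin,MDR1,20.8,1.43,21.7,1.08,93.1,1.67,90.8,4.80,1.02
Dextromethorphan,MOCK,35.5,2.09,25.9,0.91,122,8.16,98.0,7.37,0.73
Dextromethorphan,MDR1,18.8,0.12,21.9,3.18,93.6,6.54,92.1,7.25,1.17
Cannabinoid,MOCK,13.9,0.93,10.7,2.40,84.3,6.02,96.8,4.05,0.77
Cannabinoid,MDR1,18.4,2.53,13.7,0.39,106,5.62,95.2,1.58,0.75
Propranolol,MOCK,22.8,2.13,20.1,0.71,90.9,7.14,90.0,2.36,0.88
Propranolol,MDR1,16.8,0.09,16.1,1.46,80.7,1.03,89.5,3.33,0.96
Indomethacin,MOCK,16.1,2.07,18.9,0.31,109,5.97,90.2,2.95,1.18
Indomethacin,MDR1,14.9,1.29,20.3,2.74,99.7,4.24,94.2,4.85,1.36
S-071031B,MOCK,21.8,1.58,25.3,3.54,98.8,4.05,89.9,7.05,1.19
S-071031B,MDR1,14.1,1.97,26.6,4.97,85.9,1.55,92.6,4.29,1.89
Verapamil,MOCK,24.0,1.44,22.6,1.08,110,2.83,95.1,1.89,0.94
Verapamil,MDR1,9.45,0.62,47.5,4.72,106,9.56,99.2,1.78,5.03
Vinblastine,MOCK,4.33,0.21,4.16,0.32,86.5,1.69,82.2,9.37,0.96
Vinblastine,MDR1,2.84,0.27,20.4,1.81,103,9.03,103,5.71,7.20
Quinidine,MOCK,23.4,0.37,17.2,2.85,99.1,15.6,98.6,7.19,0.73
Quinidine,MDR1,2.48,1.06,42.9,2.11,98.7,14.8,111,4.42,17.3
1655,MOCK,11.12,2.33,8.63,0.86,118,7.25,99.5,18.3,0.78
1655,MDR1,2.27,0.30,36.4,3.72,117,16.0,108,13.3,16.0
Salbutamol,MOCK,BLQ,,0.21,0.02,98.1,2.21,107,2.84,\
Salbutamol,MDR1,1.88,0.35,2.66,0.21,98.2,0.36,96.2,3.69,1.42
Cimetidine,MOCK,0.69,0.07,0.28,0.07,96.9,13.3,90.4,11.5,0.41
Cimetidine,MDR1,1.32,0.31,33.9,4.30,87.4,9.65,94.2,26.3,25.7
Digoxin,MOCK,1.91,0.13,1.75,0.07,95.0,5.24,95.6,3.23,0.80
Digoxin,MDR1,1.15,0.28,7.79,0.91,109,16.0,83.9,0.36,6.90
Atenolol,MOCK,0.27,0.01,0.20,0.02,102,3.17,88.9,4.03,0.95
Atenolol,MDR1,1.06,0.09,1.35,0.15,101,3.47,107,0.78,1.27
Doxorubicin,MOCK,BLQ,,0.09,0.01,112,11.22,108,9.06,\
Doxorubicin,MDR1,0.95,0.16,3.47,0.39,109,4.57,106,0.51,3.65
Etoposide,MOCK,BLQ,,0.16,0.02,106,0.11,103,1.60,\
Etoposide,MDR1,0.75,0.10,3.68,0.22,100,2.47,99.5,2.65,4.89
Methotrexate,MOCK,BLQ,,BLQ,,85.8,4.58,86.7,17.5,\
Methotrexate,MDR1,0.55,0.10,0.45,0.05,83.3,5.67,81.4,11.2,0.81
Amitriptyline,MOCK,9.98,0.69,13.8,1.58,50.0,5.98,80.6,8.30,1.38
Amitriptyline,MDR1,6.84,0.72,12.7,1.19,43.2,2.81,78.2,5.74,1.85
Sunitinib,MOCK,9.31,0.74,6.21,0.20,49.5,3.17,80.5,5.21,0.67
Sunitinib,MDR1,2.23,0.21,21.8,1.08,64.6,4.06,91.8,1.11,9.77
Paroxetine,MOCK,7.65,0.20,14.8,0.57,54.1,1.86,73.9,2.84,1.93
Paroxetine,MDR1,5.15,0.55,10.9,0.35,45.0,0.98,60.8,1.32,2.11
Tetrandrine,MOCK,3.15,0.23,4.19,0.77,21.1,2.22,83.1,6.26,1.33
Tetrandrine,MDR1,1.55,0.29,13.0,2.24,39.1,6.10,89.9,12.94,8.40
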