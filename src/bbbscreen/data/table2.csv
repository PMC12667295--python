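compound_id,pb_plasma,pb_plasma_sd,pb_plasma_note,pb_brain,pb_brain_sd,pb_brain_note,kp_brain,kp_note,kp_uu_brain,reference
705,94.5,,a,91.8,0.51,,0.53,a,0.79,
1111,90.7,,a,97.5,0.28,,8.96,a,2.21,
1655,57.5,,a,76.9,0.29,,0.0729,a,0.0396,
Amitriptyline,,,,,,,20.15,,0.73,Friden
Antipyrine,15.0,5.22,,19.1,6.99,,0.755,,0.72,
Atenolol,,,,,,,0.07,,0.026,Friden
Atipamezole,,,,,,,4.40,,1.700,Li
Bupropion,,,,,,,9.78,,2.000,Friden
Caffeine,22.8,2.14,,28.1,11.8,,0.618,,0.576,Bohnert
Cannabinoid,>99,,,>99,,a,1.30,a,1.20,Bansal
Cimetidine,27.8,1.73,,34.5,3.03,,0.007,,0.008,
Dexmedetomidine,95.2,,a,86.7,,a,0.80,a,2.21,
Dextromethorphan,65.0,0.82,,96.7,0.33,,11.53,,0.825,
Diazepam,,,,,,,2.28,,1.07,Friden
Digoxin,,,,,,,0.029,,0.010,Mihajlica
Diphenhydramine,,,,,,,16.25,,1.05,Friden
Doxorubicin,75,,b,>99,,,0.291,,0.012,
Etoposide,97.0,,b,>99,,,0.025,,0.008,Friden
Indomethacin,,,,,,,0.01,,0.11,Friden
Lamotrigine,,,,,,,2.02,,0.880,Friden
Lidocaine,64.3,1.50,,75.0,1.01,,3.863,a,2.70,
Melatonin,33.0,,,30.0,,a,0.5,a,0.575,LeQuellec
Methotrexate,,,,,,,0.004,,0.006,Friden
Metoprolol,,,,,,,10.375,,0.64,Friden
Midazolam,97.0,,a,97.8,0.15,,2.44,a,1.416,
Modafinil,60,,b,69.2,4.06,,0.71,,0.547,
Nimodipine,95.0,,b,>99,,,2.25,,0.451,Li
Omeprazole,95.5,0.68,,67.9,13.85,,0.15,,1.095,Cheng
Paroxetine,97.9,0.07,,>99,,,3.307,,1.574,OBrien
Phenacetin,58.4,0.49,,58.1,8.76,,0.763,,0.768,
Propranolol,,,,,,,16.37,,0.61,Friden
Quinidine,,,,,,,0.32,,0.036,Nicolai
S-071031B,,,,,,,23.26,a,1.62,
Salbutamol,22.0,1.36,,68.5,1.15,,0.021,a,0.01,
Sunitinib,98.3,0.17,,>99,,,0.965,,0.563,
Tacrine,,,,,,,9.56,,0.78,Friden
Tetrandrine,,,,,,,24.3,,0.80,Wang
Tolbutamide,,,,,,,0.20,,0.706,Sugita
Tramadol,,,,,,,5.29,,1.46,Friden
Verapamil,,,,,,,0.35,,0.173,Wanek
Vinblastine,94.0,1.01,,>99,,,0.528,,0.088,
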