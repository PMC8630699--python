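subgroup,pfs_hr,pfs_ci_low,pfs_ci_high,os_hr,os_ci_low,os_ci_high
Male,0.69,0.51,0.92,0.45,0.31,0.64
Female,0.70,0.48,1.01,0.60,0.39,0.92
Age<64 yr,0.72,0.52,1.00,0.54,0.37,0.80
Age>=64 yr,0.71,0.51,0.98,0.48,0.32,0.73
BRAF mutant,1.01,0.66,1.56,0.73,0.43,1.26
NRAS mutant,0.62,0.36,1.07,0.48,0.25,0.91
BRAF & NRAS WT,0.58,0.42,0.81,0.46,0.31,0.69
ECOG PS 0,0.68,0.49,0.95,0.47,0.31,0.72
ECOG PS >=1,0.99,0.70,1.42,0.82,0.56,1.21
III/M1A/M1B,0.74,0.48,1.15,0.53,0.30,0.93
M1C/M1D,0.68,0.51,0.89,0.50,0.37,0.69
Brain metastases: No,0.79,0.52,1.18,0.51,0.31,0.82
Brain metastases: Yes,0.64,0.48,0.84,0.47,0.33,0.66
Lung metastases: No,0.73,0.54,0.98,0.54,0.38,0.78
Lung metastases: Yes,0.69,0.48,1.00,0.48,0.31,0.74
Liver metastases: No,0.68,0.45,1.04,0.59,0.37,0.93
Liver metastases: Yes,0.71,0.54,0.94,0.48,0.34,0.67
LDH = UNL,0.75,0.54,1.02,0.45,0.30,0.69
LDH > UNL,0.56,0.38,0.83,0.47,0.30,0.72
PD-(L)1 setting: Adjuvant,0.52,0.22,1.25,0.81,0.17,3.90
PD-(L)1 setting: Metastatic,0.74,0.58,0.94,0.54,0.40,0.71
Resistance: Innate,0.75,0.56,0.99,0.52,0.37,0.71
Resistance: Acquired,0.71,0.44,1.14,0.56,0.31,1.01
Best response: SD/PD,0.72,0.55,0.95,0.50,0.36,0.68
Best response: CR/PR,0.79,0.45,1.40,0.70,0.34,1.43
Best response: Not applicable,0.52,0.22,1.25,0.81,0.17,3.90
Time to progression <=3 months,0.63,0.46,0.87,0.45,0.31,0.64
Time to progression >3 months,0.75,0.53,1.05,0.52,0.34,0.81
Time from PD-(L)1 <=1 month,0.72,0.52,0.99,0.54,0.37,0.80
Time from PD-(L)1 >1 month,0.69,0.49,0.96,0.47,0.31,0.70
Interim systemic treatment: No,0.67,0.52,0.87,0.51,0.38,0.69
Interim systemic treatment: Yes,0.68,0.36,1.30,0.34,0.16,0.75
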