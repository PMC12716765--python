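pt,n,ror,ror_lo95,ror_hi95,prr,chi2,ebgm,ebgm05,ic,ic025
Product use in unapproved indication,212,5.86,5.12,6.72,5.76,835.94,5.75,5.13,2.52,2.32
Somnolence,175,5.4,4.65,6.27,5.32,615.85,5.32,4.69,2.41,2.19
Suicide attempt,150,15.3,13.02,17.98,15.08,1968.5,15.04,13.14,3.91,3.67
Insomnia,145,3.32,2.81,3.91,3.28,230.93,3.28,2.86,1.71,1.47
Weight increased,117,3.28,2.74,3.94,3.26,183.42,3.25,2.79,1.7,1.44
Anxiety,117,2.49,2.07,2.98,2.47,102.76,2.47,2.12,1.3,1.04
Depression,112,2.94,2.44,3.55,2.92,142.08,2.92,2.5,1.55,1.27
Confusional state,101,3.81,3.14,4.64,3.79,207.44,3.78,3.21,1.92,1.63
Suicidal ideation,92,6.15,5.01,7.55,6.1,392.74,6.1,5.13,2.61,2.31
Agitation,92,7.59,6.18,9.32,7.53,520.47,7.52,6.33,2.91,2.61
Completed suicide,85,6.14,4.96,7.61,6.1,362.45,6.09,5.1,2.61,2.29
Drug hypersensitivity,84,2.59,2.09,3.21,2.58,81.32,2.58,2.15,1.37,1.05
Drug interaction,81,3.12,2.51,3.88,3.1,115.72,3.1,2.58,1.63,1.31
Tremor,77,2.81,2.25,3.52,2.8,89.15,2.8,2.32,1.48,1.16
Coma,74,9.57,7.61,12.03,9.5,562.51,9.49,7.83,3.25,2.91
Intentional overdose,71,7.15,5.66,9.04,7.11,372.59,7.1,5.84,2.83,2.49
Toxicity to various agents,71,2.66,2.11,3.36,2.65,72.92,2.65,2.18,1.4,1.06
Tachycardia,67,4.65,3.65,5.91,4.62,190.18,4.62,3.78,2.21,1.86
Suspected suicide,64,111.27,86.81,142.62,110.55,6811.34,108.39,88.06,6.76,6.4
Electrocardiogram qt prolonged,61,10.54,8.2,13.56,10.48,522.68,10.47,8.48,3.39,3.02
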