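characteristic,category,count,published_percent
total,all,2954,
sex,Female,1666,56.4
sex,Male,1116,37.8
sex,Missing,172,5.8
weight_kg,<50,134,4.5
weight_kg,50-100,477,16.1
weight_kg,>100,46,1.6
weight_kg,Missing,2297,77.8
age_years,<18,92,3.1
age_years,18-64.9,1158,39.2
age_years,65-85,639,21.6
age_years,>85,153,5.2
age_years,Missing,912,30.9
occupation,Consumer,944,32.0
occupation,Health professionals,199,6.7
occupation,Lawyer,12,0.4
occupation,Medical doctor,1029,34.8
occupation,Pharmacist,203,6.9
occupation,Other health-professional,447,15.1
occupation,Missing,120,4.1
country,United States,1500,50.8
country,Switzerland,291,9.9
country,France,230,7.8
country,Japan,220,7.4
country,Canada,166,5.6
outcome,Congenital anomaly,11,0.4
outcome,Death,316,10.7
outcome,Disability,62,2.1
outcome,Hospitalization,779,26.4
outcome,Life-threatening,127,4.3
outcome,Other,682,23.1
outcome,Required intervention,9,0.3
outcome,Missing,968,32.8
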