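trial_id,cancer_type,regimen,drug_class,control_type,assay_clone,scoring_method,n_low_pdl1,n_total,pct_printed,ipd_available
KEYNOTE-407,NSCLC,combination,anti-PD-1,placebo + chemo,22C3,TPS,194,559,34.7,1
IMpower150,NSCLC,combination,anti-PD-L1,bevacizumab + chemo,SP142,TPS&IPS,338,800,42.2,1
CheckMate 214,RCC,combination,anti-PD-1,sunitinib,28-8,TPS,562,839,67.0,1
IMmotion151,RCC,combination,anti-PD-L1,sunitinib,SP142,IPS,553,915,60.4,1
IMpower130,NSCLC,combination,anti-PD-L1,chemo,SP142,TPS&IPS,356,723,49.2,0
JAVELIN Renal 101,RCC,combination,anti-PD-L1,sunitinib,SP263,IPS,326,886,36.8,1
IMvigor130,UC,combination,anti-PD-L1,placebo + chemo,SP142,IPS,392,1213,32.3,0
IMspire150,melanoma,combination,anti-PD-L1,placebo + vemurafenib + cobimetinib,SP142,IPS,171,514,33.3,0
IMpower131,NSCLC,combination,anti-PD-L1,chemo,SP142,TPS&IPS,331,683,48.5,0
KEYNOTE-426,RCC,combination,anti-PD-1,sunitinib,22C3,CPS,321,861,37.3,0
KEYNOTE-604,SCLC,combination,anti-PD-1,placebo + chemo,22C3,CPS,174,453,38.4,0
IMpassion130,TNBC,combination,anti-PD-L1,placebo + chemo,SP142,IPS,533,902,61.3,1
CheckMate 649,GC,combination,anti-PD-1,chemo,28-8,CPS,342,2394,14.3,1
IMpower133,SCLC,combination,anti-PD-L1,placebo + chemo,SP263,TPS&IPS,65,403,16.2,1
ESCORT-1st,ESCC,combination,anti-PD-1,placebo + chemo,28-8,TPS,256,598,43.0,1
NCT03581786,NPC,combination,anti-PD-1,placebo + chemo,JS311,TPS&IPS,45,289,15.6,1
IMpassion131,TNBC,combination,anti-PD-L1,placebo + chemo,SP142,IPS,359,651,55.1,1
JAVELIN Gastric 100,GC,mono,anti-PD-L1,chemo,22C3,TPS,362,499,72.5,1
JAVELIN Ovarian 100,OC,combination,anti-PD-L1,chemo then observation,SP263,TPS&IPS,326,998,32.7,1
IMagyn050,OC,combination,anti-PD-L1,placebo + bevacizumab + chemo,SP142,IPS,517,1301,39.7,1
IMpower132,NSCLC,combination,anti-PD-L1,chemo,SP142,TPS&IPS,163,578,28.2,1
CheckMate 451,SCLC,combination,anti-PD-1,placebo,28-8,CPS,191,834,22.9,1
CheckMate 9LA,NSCLC,combination,anti-PD-1,chemo,28-8,TPS,264,719,36.7,1
KEYNOTE-189,NSCLC,combination,anti-PD-1,placebo + chemo,22C3,TPS,190,616,30.8,1
TASUKI-52,NSCLC,combination,anti-PD-1,placebo + chemo,28-8,TPS,240,750,32.0,1
CameL,NSCLC,combination,anti-PD-1,chemo,22C3,TPS,67,402,16.7,1
CLEAR,RCC,combination,anti-PD-1,sunitinib,22C3,CPS,215,612,35.1,0
KEYNOTE-361,UC,mono,anti-PD-1,chemo,22C3,CPS,341,659,51.7,0
KEYNOTE-590,ESCC,combination,anti-PD-1,placebo + chemo,22C3,CPS,347,749,46.3,1
KEYNOTE-048,HNSCC,combination,anti-PD-1,cetuximab + chemo,22C3,CPS,128,882,14.5,1
KEYNOTE-355,TNBC,combination,anti-PD-1,placebo + chemo,22C3,CPS,211,847,24.9,1
CheckMate 648,ESCC,combination,anti-PD-1,chemo,28-8,TPS,497,970,51.2,1
CheckMate 227,NSCLC,combination,anti-PD-1,chemo,28-8,TPS,550,1739,31.6,1
CheckMate 743,MPM,combination,anti-PD-1,chemo,28-8,TPS,135,605,22.3,1
PACIFIC,NSCLC,mono,anti-PD-L1,CRT then placebo,SP263,TPS,148,713,20.8,1
CheckMate 067,melanoma,combination,anti-PD-1,ipilimumab,28-8,TPS,353,945,35.4,1
CheckMate 459,HCC,mono,anti-PD-1,sorafenib,28-8,TPS,595,743,80.1,1
GEMSTONE-302,NSCLC,combination,anti-PD-L1,placebo + chemo,SP263,TPS,188,479,39.2,1
IMbrave150,HCC,combination,anti-PD-L1,sorafenib,SP142,TPS&IPS,77,503,15.3,0
EMPOWER-Lung 3,NSCLC,combination,anti-PD-L1,placebo + chemo,SP263,TPS,139,466,29.8,0
ATTRACTION-4,GC,combination,anti-PD-1,placebo + chemo,28-8,TPS,610,724,84.2,0
ORIENT-15,ESCC,combination,anti-PD-1,placebo + chemo,22C3,TPS,297,659,45.1,1
CheckMate 9ER,RCC,combination,anti-PD-1,sunitinib,28-8,TPS,472,651,72.5,0
CAPSTONE-1,SCLC,combination,anti-PD-L1,placebo + chemo,22C3,TPS,396,462,85.7,0
ASTRUM-005,SCLC,combination,anti-PD-1,placebo + chemo,22C3,TPS,469,585,81.2,0
POSEIDON,NSCLC,combination,anti-PD-L1,chemo,SP263,TPS,368,1013,36.3,0
COMBI-i,melanoma,combination,anti-PD-1,placebo + dabrafenib + trametinib,28-8,TPS,213,532,40.0,1
JUPITER-06,ESCC,combination,anti-PD-1,placebo + chemo,JS311,TPS,193,295,65.4,1
NEPTUNE,NSCLC,combination,anti-PD-L1,chemo,SP263,IPS,195,823,23.7,1
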