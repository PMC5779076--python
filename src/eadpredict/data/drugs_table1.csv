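name,pIC50_INa,pIC50_ICaL,pIC50_hERG,pIC50_IKs,pIC50_IpNa,pIC50_Ito,pIC50_IK1,eftpc_nM
Ajmaline,5.0862,4.1487,5.9830,,,5.5751,,17103
Amiodarone,4.3936,6.5686,7.5229,5.7595,5.1739,5.4250,,0.5
Amitriptyline,4.6990,4.9355,5.4841,5.5627,5.3533,5.0000,,41
Azimilide,4.7212,4.7496,7.0000,5.8539,,,,70
Bepridil,5.4318,6.6757,6.2218,5.0000,5.7414,5.1805,,33
Chlorpromazine,5.5528,5.5229,5.8297,,5.3410,4.7959,5.2147,38
Cibenzoline,5.1079,4.5229,4.6459,4.9101,4.3318,,,976
Cisapride,4.8327,4.7959,8.1871,5.4698,,5.0301,,4.9
Clozapine,,,5.6021,,,,,1603
Desipramine,5.8182,5.7673,5.8570,,,,,108
Diltiazem,4.8477,7.2676,5.1314,,,4.5346,,122
Disopyramide,,,5.7447,4.0910,,4.6799,,742
dl-Sotalol,,,3.5560,,,,,14733
Dofetilide,3.5229,4.5735,8.3010,,,,,2
Flecainide,5.1871,4.5918,5.7959,,5.4685,5.1079,,753
Fluvoxamine,4.4045,5.3098,5.4202,,,,,264
Halofantrine,,,7.6655,,,,,0.5
Imipramine,5.4437,5.0915,5.4685,,,4.3010,,106
Loratadine,,,5.0809,,,,,0.45
Methadone,4.9508,4.5735,5.3188,,,,,507
Mexiletine,4.3665,4.0000,4.3010,,4.7545,,,4129
Mibefradil,6.0088,6.8069,5.7447,,5.4403,,,12
Nifedipine,4.4318,7.2218,3.5607,3.4437,,4.8633,,7.7
Nitrendipine,4.6655,7.6021,5.0000,,,5.1135,,3.02
Ondansetron,4.0531,4.6468,6.0915,,4.7171,,,899.88
Pentamidine,,,3.6882,,,,6.7696,10
Phenytoin,4.3098,3.9872,4.0000,,,,,7000
Pimozide,7.2676,6.6198,7.8239,,,,,0.43
Prenylamine,5.5986,5.9066,7.1871,,,,,17
Propafenone,5.9245,5.7447,6.3565,,5.3940,5.3188,5.1487,241
Propranolol,5.6778,4.7447,5.5485,,,,,26
Quetiapine,4.7721,4.9830,5.2392,,,,,33
Quinidine,4.7799,4.8069,6.5229,5.3099,,3.0580,3.6990,3237
Ranolazine,3.5317,3.5287,4.9393,2.7212,5.1871,,,3200
Risperidone,3.9914,4.1367,6.2218,,,,,1.81
Sertindole,5.6383,5.0506,7.8539,6.0555,,5.3979,,1.59
Tedisamil,4.6990,,5.6021,,,5.3565,,85
Terfenadine,6.0128,6.4260,8.0506,5.6990,,,,9
Terodiline,,4.8182,8.3979,4.5229,,,5.1549,12
Thioridazine,5.7375,5.8861,7.4815,4.8539,,,,979
Verapamil,4.3820,7.0000,6.8447,,,2.5796,,81
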