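name,risk_category,provenance
Ajmaline,2,confirmed_in_text
Amiodarone,2,default_redfern_mirams
Amitriptyline,3,default_redfern_mirams
Azimilide,2,confirmed_in_text
Bepridil,2,default_redfern_mirams
Chlorpromazine,3,default_redfern_mirams
Cibenzoline,5,confirmed_in_text
Cisapride,2,confirmed_in_text
Clozapine,4,default_redfern_mirams
Desipramine,4,confirmed_in_text
Diltiazem,5,default_redfern_mirams
Disopyramide,2,default_redfern_mirams
dl-Sotalol,2,default_redfern_mirams
Dofetilide,2,default_redfern_mirams
Flecainide,3,default_redfern_mirams
Fluvoxamine,4,confirmed_in_text
Halofantrine,3,default_redfern_mirams
Imipramine,4,default_redfern_mirams
Loratadine,5,default_redfern_mirams
Methadone,3,default_redfern_mirams
Mexiletine,5,default_redfern_mirams
Mibefradil,4,default_redfern_mirams
Nifedipine,5,default_redfern_mirams
Nitrendipine,5,default_redfern_mirams
Ondansetron,2,confirmed_in_text
Pentamidine,3,default_redfern_mirams
Phenytoin,5,default_redfern_mirams
Pimozide,3,default_redfern_mirams
Prenylamine,2,default_redfern_mirams
Propafenone,4,default_redfern_mirams
Propranolol,5,default_redfern_mirams
Quetiapine,4,default_redfern_mirams
Quinidine,2,confirmed_in_text
Ranolazine,4,confirmed_in_text
Risperidone,4,default_redfern_mirams
Sertindole,2,default_redfern_mirams
Tedisamil,2,default_redfern_mirams
Terfenadine,2,confirmed_in_text
Terodiline,2,confirmed_in_text
Thioridazine,3,confirmed_in_text
Verapamil,5,default_redfern_mirams
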