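chemical,pd_mg_kg_day,source_code,molar_basis_note
"2,4,5-T",0.01,1,0
"2,4,5-TP",0.008,1,0
"2,4-D",0.005,2,0
"2,4-DB",0.03,2,0
"2,6 Diethylaniline",0.006,3,1
3-Hydroxycarbofuran,0.00006,2,1
Acetochlor,0.02,3,0
Acifluorfen,0.004,2,0
Alachlor,0.01,2,0
Aldicarb,0.00027,3,0
Aldicarb sulfone,0.00027,3,0
Aldicarb sulfoxide,0.00027,3,0
alpha-HCH,0.008,3,0
Atrazine,0.0019,2,0
Azinphos-methyl,0.00149,2,0
Benfluralin,0.005,2,0
Bentazon,0.03,2,0
Bromacil,0.1,2,0
Bromoxynil,0.015,2,0
Butylate,0.05,2,0
Carbaryl,0.01,2,0
Carbofuran,0.00006,2,0
Chloramben methyl ester,0.014,4,0
Chlorothalonil,0.02,2,0
Chlorpyrifos,0.00003,2,0
cis-Permethrin,0.25,2,0
Clopyralid,0.15,3,0
Cyanazine,0.00026,5,0
Dacthal,0.01,2,0
Dacthal monoacid,0.01,2,0
Diethyl atrazine,0.0018,2,1
Diazinon,0.0002,2,0
Dicamba,0.45,2,0
Dichlobenil,0.015,2,0
Dichlorprop,0.036,2,0
Dieldrin,0.00005,6,0
Dinoseb,0.001,1,0
Dinitro-o-cresol,0.004,6,0
Disulfoton,0.00013,2,0
Diuron,0.003,2,0
EPTC,0.0025,2,0
Ethalfluralin,0.04,2,0
Ethoprop,0.0001,2,0
Fluometuron,0.005,2,0
Fonofos,0.002,2,0
gamma-HCH,0.0003,1,0
Linuron,0.0077,2,0
Malathion,0.07,2,0
MCPA,0.0044,2,0
MCPB,0.015,2,0
Methiocarb,0.005,2,0
Methomyl,0.008,2,0
Metolachlor,0.1,2,0
Metribuzin,0.013,2,0
Molinate,0.001,3,0
Napropamide,0.12,2,0
Norflurazon,0.015,2,0
Oryzalin,0.12,2,0
Oxamyl,0.001,2,0
"p,p'-DDE",0.0005,3,0
Parathion,0.006,7,0
Parathion-methyl,0.00002,2,0
Pebulate,0.0007,2,0
Pendimethalin,0.1,2,0
Phorate,0.00017,2,0
Picloram,0.2,2,0
Prometon,0.05,2,0
Pronamide,0.027,2,0
Propachlor,0.054,2,0
Propanil,0.009,2,0
Propargite,0.04,2,0
Propham,0.02,1,0
Propoxur,0.005,2,0
Simazine,0.0018,2,0
Tebuthiuron,0.07,2,0
Terbacil,0.013,2,0
Terbufos,0.00005,2,0
Thiobencarb,0.01,2,0
Triallate,0.025,2,0
Triclopyr,0.05,2,0
Trifluralin,0.024,2,0
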