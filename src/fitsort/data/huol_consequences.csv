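alternative,cost,demand,lead_time,criticality,volume
"Alteplase, 50 mg, lyophylic powder",2022.99,5,13,3,0.0004233
"Calcium folinate, 50 mg, lyophylic powder",10.72,250,48,2,0.0046800
"Cefazoline sodium, 1 g, lyophylic powder",16.28,948,4,2,0.0022298
"Ceftriaxone sodium, 1 g, lyophylic powder, indovenous",6.51,1067,20,2,0.0035784
"Concentrated enzyme detergent - liter",48.00,83,28,3,0.0196070
"Disposable syringe 20 ml without needle - luer lock",0.44,2655,28,3,0.0311555
"Double lumen catheter for long permanent HD. 14.5FR x 36 cm",900.00,3,13,2,0.0018360
"Double lumen subclavia access catheter - 7F x 20 cm",69.81,60,9,3,0.0106000
"Enoxaparin sodium, 40 mg/0.4 ml, filled syringe",12.92,1529,5,3,0.0329586
"Ethyl alcohol 70% P/V - 100 ml",1.19,2946,57,2,0.0090137
"Ethyl alcohol 70% P/V - FR 250 ml",2.55,2594,43,2,0.0380800
"Ethyl alcohol, 70%, gel - FR 500 g",7.10,351,11,2,0.0285120
"Face protection mask, respirator type - N95/PFF-2",6.46,1047,27,3,0.0038850
"Fentanyl citrate, 0.05 mg/ml, injectable solution, 5 ml",1.85,1174,16,2,0.0004620
"Glove for non-surgical latex procedure - small size",0.38,23298,15,2,0.0286202
"Glutaraldehyde aqueous solution for general use 2%",190.00,21,36,2,0.0314712
"Human albumin, 20%, injectable solution, 50 ml",99.50,476,14,3,0.0065340
"Low pressure extender male and female connector - 20 cm",4.90,523,18,3,0.0302568
"Medium-large clip, for laparoscopic clip",19.79,156,19,3,0.0009570
"Meropenem, 1 g, lyophylic powder",20.44,1433,20,3,0.0010129
"Methylcellulose, 2%, intraocular solution, 1.5 ml",29.60,120,21,1,0.0002550
"Myelogram aspiration needle 16 g - 6 cm to 7 cm",60.00,33,7,2,0.0060204
"Nalbufine chloridrate, 10 mg/ml, injectable solution, 1 ml",9.28,232,26,3,0.0003931
"Natural latex surgical glove - no. 8.0 - pair",1.35,1818,33,3,0.0355320
"Oxacillin, 500 mg, lyophylic powder",1.75,2347,12,3,0.0017922
"Oxaliplatin, 100 mg, lyophylic powder",90.00,29,14,2,0.0016027
"Percutaneous radial introductor with hemostatic valve - 5F - 11 cm",44.68,345,6,3,0.0058332
"Piperacillin sodium + tazobactam sodium (4 g + 500 mg), lyophylic powder",16.24,1268,28,2,0.0018198
"Radiographic film, size 35 x 43 cm for laser printer",4.41,647,28,3,0.0257418
"Radiological contrast, non-ionic, low osmolarity, 300 to 320 mg iodine/ml, injectable solution, 100 ml",53.07,527,7,3,0.0003856
"Radiological contrast, non-ionic, low osmolarity, ioversol based, 320 mg iodine/ml, injectable solution, 125 ml",232.52,45,5,1,0.0267400
"Rectangular surgical mask with strips - 3 layers",2.32,29155,57,3,0.0655928
"Remifentanil chloridrate, 2 mg, lyophylic powder",36.60,72,15,1,0.0001599
"Sevofluran, inhaled anesthetic, 250 ml",295.00,47,10,3,0.0005152
"Small clip for laparoscopic clipper",30.00,45,13,3,0.0009660
"Sodium chloride, 0.9%, injectable solution, closed system, 100 ml",1.59,11031,17,3,0.0218919
"Stabilizer for coronary surgery with suction mechanism",2042.93,3,18,3,0.0130816
"Sterile hydrophyl gaze compress - 7.5 cm x 7.5 cm - package with 10 units",0.39,26007,8,3,0.0461448
"Straight scalpel for paracentesis (auxiliary incision) - 15 degrees",22.00,75,19,3,0.0013440
"Surgical glove in natural latex - no. 7.0",1.33,4342,33,3,0.0362952
"Surgical glove in natural latex - no. 7.5",1.00,5089,47,3,0.0357840
"Surgical trepanning tool for receiver cornea - 8.0 mm",360.00,5,20,2,0.0007313
"Suventanil citrate, 50 mcg/ml, injectable, 1 ml",20.12,125,13,1,0.0006350
"Syringe desc. for insulin 1 ml, with needle",0.49,43391,33,3,0.0381779
"Team for administration of parenteral solutions by infusion pump",19.74,1600,28,3,0.0365381
"Thyrofibana chloridrate, 0.25 mg/ml, injectable solution, 50 ml",876.00,26,42,3,0.0002125
"Tigecycline, 50 mg, lyophylic powder",184.34,48,15,3,0.0003060
"Voriconazole, 200 mg, lyophylic powder",148.88,91,6,1,0.0046406
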