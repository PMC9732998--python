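alternative,s1,s2,classes
"Alteplase, 50 mg, lyophylic powder",0.41873197,0.48394727,B
"Concentrated enzyme detergent - liter",0.42028734,0.56357202,B
"Disposable syringe 20 ml without needle - luer lock",0.47157452,0.58919982,B
"Syringe desc. for insulin 1 ml, with needle",0.49378278,0.50515474,B
"Double lumen subclavia access catheter - 7F x 20 cm",0.41982870,0.59089520,B
"Enoxaparin sodium, 40 mg/0.4 ml, filled syringe",0.44912142,0.59592977,B
"Face protection mask, respirator type - N95/PFF-2",0.43951006,0.59574410,B
"Glutaraldehyde aqueous solution for general use 2%",0.20970497,0.39418957,M
"Human albumin, 20%, injectable solution, 50 ml",0.42812398,0.59329625,B
"Low pressure extender male and female connector - 20 cm",0.42906119,0.57208599,B
"Medium-large clip, for laparoscopic clip",0.42174300,0.59443520,B
"Meropenem, 1 g, lyophylic powder",0.44720712,0.61021685,B
"Methylcellulose, 2%, intraocular solution, 1.5 ml",0.00233305,0.31348742,M
"Nalbufine chloridrate, 10 mg/ml, injectable solution, 1 ml",0.42325848,0.58929397,B
"Natural latex surgical glove - no. 8.0 - pair",0.45488425,0.56840435,B
"Oxacillin, 500 mg, lyophylic powder",0.46543282,0.63119120,B
"Percutaneous radial introductor with hemostatic valve - 5F - 11 cm",0.41931025,0.54734040,B
"Radiographic film, size 35 x 43 cm for laser printer",0.43153382,0.56771800,B
"Radiological contrast, non-ionic, low osmolarity, 300 to 320 mg iodine/ml, injectable solution, 100 ml",0.42914095,0.61045399,B
"Radiological contrast, non-ionic, low osmolarity, ioversol based, 320 mg iodine/ml, injectable solution, 125 ml",0.00083750,0.28998712,M
"Rectangular surgical mask with strips - 3 layers",0.87555622,1.00000000,W
"Remifentanil chloridrate, 2 mg, lyophylic powder",0.00137590,0.31882647,M
"Sevofluran, inhaled anesthetic, 250 ml",0.41956947,0.58533668,B
"Small clip for laparoscopic clipper",0.41952959,0.59862967,B
"Stabilizer for coronary surgery with suction mechanism",0.41869209,0.45209266,B
"Sterile hydrophyl gaze compress - 7.5 cm x 7.5 cm - package with 10 units",0.90501007,0.93722708,W
"Straight scalpel for paracentesis (auxiliary incision) - 15 degrees",0.42012781,0.59283364,B
"Surgical glove in natural latex - no. 7.0",0.50521428,0.60111437,B
"Surgical glove in natural latex - no. 7.5",0.52010990,0.59678555,B
"Suventanil citrate, 50 mcg/ml, injectable, 1 ml",0.00243275,0.32221785,M
"Team for administration of parenteral solutions by infusion pump",0.45053720,0.56860837,B
"Thyrofibana chloridrate, 0.25 mg/ml, injectable solution, 50 ml",0.41915072,0.51448538,B
"Tigecycline, 50 mg, lyophylic powder",0.41958941,0.58735622,B
"Voriconazole, 200 mg, lyophylic powder",0.00011964,0.30529318,M
"Calcium folinate, 50 mg, lyophylic powder",0.21427137,0.42274553,B|M
"Cefazoline sodium, 1 g, lyophylic powder",0.22818990,0.48049510,B|M
"Ceftriaxone sodium, 1 g, lyophylic powder, indovenous",0.23056283,0.46447774,B|M
"Double lumen catheter for long permanent HD. 14.5FR x 36 cm",0.20934604,0.40239618,B|M
"Ethyl alcohol 70% P/V - 100 ml",0.26803118,0.44529085,B|M
"Ethyl alcohol 70% P/V - FR 250 ml",0.26101210,0.42631294,B|M
"Ethyl alcohol, 70%, gel - FR 500 g",0.21628537,0.43957048,B|M
"Fentanyl citrate, 0.05 mg/ml, injectable solution, 5 ml",0.23269647,0.47352129,B|M
"Glove for non-surgical latex procedure - small size",0.67386186,0.73996574,W|B
"Myelogram aspiration needle 16 g - 6 cm to 7 cm",0.20994426,0.45862365,B|M
"Oxaliplatin, 100 mg, lyophylic powder",0.20986450,0.45367685,B|M
"Piperacillin sodium + tazobactam sodium (4 g + 500 mg), lyophylic powder",0.23457088,0.45983831,B|M
"Sodium chloride, 0.9%, injectable solution, closed system, 100 ml",0.63859685,0.72103789,W|B
"Surgical trepanning tool for receiver cornea - 8.0 mm",0.20938593,0.43064704,B|M
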