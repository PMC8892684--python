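citation_id,diet_label,animal_desc,n_animals,bw,dmi,cp,ndf,ee,starch,tdn,ge,de,me,me_de_ratio,ch4_pct_de,urine_pct_de
study_02,Concentrate-based diet - day 116 of gestation,MARC III pregnant heifer,7,432,4.58,14.60,26.60,3.73,54.32,78.8,4.21,3.21,2.79,0.8707,7.5,6.1
study_02,Concentrate-based diet - day 172 of gestation,MARC III pregnant heifer,7,468,5.13,14.60,26.60,3.73,54.32,78.8,4.11,2.94,2.55,0.8675,8.6,5.3
study_02,Concentrate-based diet - day 235 of gestation,MARC III pregnant heifer,7,520,6.04,14.60,26.60,3.73,54.32,78.8,4.22,3.21,2.80,0.8711,7.7,4.6
study_02,Forage-based diet - day 116 of gestation,MARC III pregnant heifer,7,430,6.70,15.10,48.70,2.11,7.49,57.8,4.25,2.48,2.04,0.8253,10.2,7.2
study_02,Forage-based diet - day 172 of gestation,MARC III pregnant heifer,7,454,7.04,15.10,48.70,2.11,7.49,57.8,4.20,2.39,1.97,0.8274,10.7,6.5
study_02,Forage-based diet - day 235 of gestation,MARC III pregnant heifer,7,498,8.27,15.10,48.70,2.11,7.49,57.8,4.35,2.43,2.02,0.8308,10.9,6.0
study_07,Control main effect,British crossbred steers,8,480,6.77,11.80,21.70,3.50,49.20,79.4,4.16,3.06,2.80,0.9150,3.3,4.3
study_07,Yeast main effect,British crossbred steers,8,484,6.77,11.80,21.70,3.50,49.20,79.4,4.16,3.16,2.93,0.9272,3.0,4.2
study_07,Thermoneutral main effect,British crossbred steers,8,483,7.10,11.80,21.70,3.50,49.20,79.4,4.16,3.06,2.80,0.9150,2.8,4.2
study_07,Heat stressed - main effect,British crossbred steers,8,480,6.43,11.80,21.70,3.50,49.20,79.4,4.16,3.16,2.92,0.9241,3.6,4.3
study_09,0% dry-rolled corn diet,Angus yearling steers,10,495,7.54,11.99,40.60,3.73,21.10,63.9,4.24,2.67,2.33,0.8727,8.1,4.5
study_09,22.5% dry-rolled corn diet,Angus yearling steers,10,515,8.05,12.62,39.31,3.37,24.20,68.3,4.22,2.69,2.31,0.8587,10.4,4.1
study_09,45% dry-rolled corn diet,Angus yearling steers,10,507,8.65,12.61,35.15,3.15,26.72,72.8,4.27,2.80,2.43,0.8679,9.5,3.8
study_09,67.5% dry-rolled corn diet,Angus yearling steers,10,521,7.78,12.82,28.23,3.02,36.46,78.0,4.22,2.90,2.58,0.8897,7.6,3.7
study_09,83.8% dry-rolled corn diet,Angus yearling steers,10,526,8.52,12.49,27.95,2.90,45.26,83.2,4.29,3.15,2.89,0.9175,5.1,3.0
study_18,Dry-rolled corn control,Angus steers,8,475,7.23,15.02,13.87,3.00,56.85,82.5,4.40,3.22,3.01,0.9343,4.6,2.0
study_18,Dry-rolled corn + 2% corn oil,Angus steers,8,471,7.32,15.02,13.46,5.61,54.50,84.3,4.54,3.31,3.11,0.9409,4.1,1.7
study_18,Dry-rolled corn + 4% corn oil,Angus steers,8,481,6.99,15.02,13.23,7.72,52.60,86.1,4.67,3.34,3.16,0.9465,3.3,2.0
study_18,Dry-rolled corn + 6% corn oil,Angus steers,8,489,6.90,15.09,13.23,8.71,51.45,87.9,4.80,3.44,3.27,0.9515,3.1,1.8
study_20,Corn stalk diet - day 14,MARC III heifers,8,448,6.01,8.63,66.81,2.34,4.11,57.1,3.96,1.84,1.39,0.7545,14.4,10.1
study_20,Monensin corn stalk diet - day 14,MARC III heifers,8,486,5.95,8.63,66.81,2.34,4.11,57.1,3.95,1.84,1.41,0.7673,13.7,9.5
study_20,Corn stalk diet - day 42,MARC III heifers,8,457,5.30,8.63,66.81,2.34,4.11,57.1,3.91,1.86,1.39,0.7465,15.5,9.9
study_20,Monensin corn stalk diet - day 42,MARC III heifers,8,488,5.59,8.63,66.81,2.34,4.11,57.1,3.91,1.96,1.53,0.7794,14.1,8.1
study_20,Corn stalk diet - day 161,MARC III heifers,8,525,8.22,8.63,66.81,2.34,4.11,57.1,3.96,2.08,1.71,0.8195,10.3,8.5
study_20,Monensin corn stalk diet - day 161,MARC III heifers,8,556,8.04,8.63,66.81,2.34,4.11,57.1,3.97,2.06,1.67,0.8119,10.6,8.1
study_22,Steam-flaked corn diet - 1x maintenance,Angus cross steers,12,262,2.29,13.80,19.80,4.60,49.90,88.4,4.41,3.65,3.19,0.8736,7.7,5.1
study_22,Steam-flaked corn diet + excess CP - 1x maintenance,Angus cross steers,12,261,2.30,19.50,19.40,3.50,44.80,87.5,4.53,3.86,3.32,0.8615,7.6,6.5
study_22,Steam-flaked corn diet - 2x maintenance,Angus cross steers,12,391,6.15,13.80,19.80,4.60,49.90,88.4,4.41,3.73,3.42,0.9173,4.7,3.6
study_22,Steam-flaked corn diet + excess CP - 2x maintenance,Angus cross steers,12,391,6.23,19.50,19.40,3.50,44.80,87.5,4.53,3.88,3.55,0.9148,4.1,4.4
study_24,10% Cassava pulp diet,Native Thai beef cattle,6,148,2.74,9.90,63.20,5.90,8.83,59.3,4.13,2.65,2.32,0.8750,10.5,2.3
study_24,30% Cassava pulp diet,Native Thai beef cattle,6,134,2.75,9.70,53.60,5.90,20.31,65.6,4.25,3.02,2.72,0.9014,8.1,1.4
study_24,50% Cassava pulp diet,Native Thai beef cattle,6,138,3.01,9.70,45.20,5.90,31.80,72.0,4.24,3.22,2.97,0.9211,6.9,1.0
study_39,Control - no supplement,British crossbred steers,6,212,4.79,27.23,18.87,2.28,0,69.5,3.73,2.85,2.48,0.8702,8.9,4.3
study_39,Steam-flaked corn + monensin supplement,British crossbred steers,6,214,4.50,24.08,16.58,2.30,12.36,70.0,3.00,3.00,2.64,0.8808,7.9,4.1
study_40,1.1x maintenance,Native Thai beef cattle,5,269,3.50,10.60,36.30,3.50,30.90,69.3,4.10,2.99,2.51,0.8395,13.7,11.5
study_40,1.1x maintenance (period 2),Native Thai beef cattle,5,288,4.90,10.60,36.30,3.50,30.90,69.3,4.24,3.01,2.56,0.8505,12.2,10.8
study_40,1.1x maintenance (period 3),Native Thai beef cattle,5,324,5.50,10.60,36.30,3.50,30.90,69.3,4.21,3.07,2.64,0.8599,11.6,10.1
study_44,Control,Beef steers,10,449,3.47,13.84,15.65,6.32,53.30,88.9,4.81,3.81,3.69,0.9685,2.5,0.7
study_44,Zilpaterol,Beef steers,10,455,3.47,13.84,15.65,6.32,53.30,88.9,4.80,3.87,3.72,0.9612,3.2,0.6
study_45,Control corn silage diet,Chinese indigenous Wandong bulls,4,273,5.10,11.10,50.50,3.18,37.37,71.9,4.19,2.77,2.36,0.8497,11.0,4.0
study_45,Control with 10% rice straw replacement,Chinese indigenous Wandong bulls,4,273,5.10,10.71,52.50,3.00,33.60,68.9,4.16,2.68,2.30,0.8566,11.0,3.4
study_45,Control with 30% rice straw replacement,Chinese indigenous Wandong bulls,4,273,5.10,9.91,56.30,2.65,26.14,62.8,4.09,2.43,2.04,0.8382,11.3,5.0
study_45,Control with 60% rice straw replacement,Chinese indigenous Wandong bulls,4,273,5.10,8.71,62.10,2.31,14.91,53.8,3.98,2.02,1.68,0.8306,12.1,4.7
study_45,Control corn silage diet (wheat straw series),Chinese indigenous Wandong bulls,4,276,5.10,11.10,50.50,3.18,37.37,71.9,4.19,2.69,2.31,0.8571,10.9,3.4
study_45,Control with 10% wheat straw replacement,Chinese indigenous Wandong bulls,4,276,5.10,10.57,53.50,2.97,33.60,69.6,4.18,2.66,2.26,0.8519,11.2,3.7
study_45,Control with 30% wheat straw replacement,Chinese indigenous Wandong bulls,4,276,5.10,9.49,59.30,2.56,26.14,65.0,4.15,2.40,2.03,0.8460,11.7,4.0
study_45,Control with 60% wheat straw replacement,Chinese indigenous Wandong bulls,4,276,5.10,7.88,68.10,1.94,14.91,58.2,4.11,2.01,1.68,0.8364,12.0,4.4
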