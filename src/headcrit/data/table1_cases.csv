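case_id,vru_type,gender,stature_cm,weight_kg,age,vehicle_brand_model,vehicle_weight_kg,vehicle_length_mm,vehicle_width_mm,vehicle_height_mm,impact_speed_vehicle_kmh,impact_speed_vru_kmh
1,pedestrian,male,171,80,17,Volkswagen Jetta,1490,4428,1660,1420,30.0,2.1
2,pedestrian,male,172,60,20,Honda Accord,1442,4814,1821,1463,17.1,1.1
3,pedestrian,male,174,70,50,Volkswagen Jetta,1490,4428,1660,1420,37,0
4,pedestrian,male,173,68,63,Volkswagen Golf,1275,4400,1735,1470,43.2,5.0
5,pedestrian,male,176,76,35,Mercedes E-Class,1455,4800,1800,1400,46.8,7.0
6,pedestrian,male,180,77,57,Opel Astra,1150,3817,1646,1440,37.4,1.0
7,pedestrian,male,153,61,89,Volkswagen Passat,1850,4669,1740,1466,58.7,3.2
8,pedestrian,male,170,55,42,Volkswagen Jetta,1490,4428,1660,1420,43.6,6.5
9,pedestrian,male,176,75,50,Volkswagen Tiguan,1545,4506,1809,1685,48,5
10,pedestrian,male,174,75,52,Volkswagen Passat,1590,4789,1765,1470,40,5
11,pedestrian,male,166,65,70,Volkswagen Lavida,1285,4608,1743,1465,36,0
12,pedestrian,male,159,50,72,Volkswagen Polo,1270,4187,1650,1465,35,0
13,pedestrian,male,168,75,68,BYD F3,1170,4325,1705,1490,30,3.6
14,pedestrian,female,154,48,78,Zotye T600,2000,4648,1893,1686,36,0
15,pedestrian,male,175,70,56,Volkswagen Passat,1850,4789,1765,1470,70,5
16,pedestrian,male,158,55,79,Chevrolet Aveo,1210,4399,1735,1517,55,3
17,pedestrian,male,170,60,79,Hyundai Elantra,1348,4543,1777,1490,91,12
18,cyclist,female,157,60,55,Mazda Axela,1286,4461,1795,1474,30,10.5
19,cyclist,male,168,67,63,Geely Meiri,1270,4150,1620,1450,30,15.8
20,cyclist,male,170,60,54,Dongfeng Sokon,1576,3795,1560,1925,16.5,9.7
21,cyclist,male,170,80,58,Volkswagen Santana,1540,4595,1750,1430,34.7,7.2
22,cyclist,male,175,70,57,Iveco,2325,4845,2000,2500,40,4.3
23,cyclist,male,170,65,67,BAIC Hyosow S3,1335,4380,1730,1760,40.3,18.7
24,cyclist,male,158,49,65,Volkswagen Santana,1540,4595,1750,1430,31,5.5
25,cyclist,female,158,48,42,Volkswagen Santana,1540,4595,1750,1430,22,7.2
26,cyclist,male,165,60,65,Audi A4L,1565,4818,1843,1432,35,4.3
27,cyclist,female,161,45,23,Volkswagen Santana,1540,4595,1750,1430,34.7,0
28,cyclist,male,165,55,62,Volkswagen Jetta,1500,4428,1660,1420,40,7.2
29,cyclist,female,152,55,50,Wu Ling Sunshine,1030,3730,1510,1860,70,10.6
30,electric_two_wheeler,female,155,40,13,Mitsubishi Outlander,1500,4695,1810,1680,35,3.6
31,electric_two_wheeler,male,173,75,43,Hyundai Elantra,1236,4542,1775,1490,60,10.8
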