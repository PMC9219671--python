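seminal,lung,heart,assignment,residue,reported_band,ref
324,,328,,,,
344,,346,,,,
421,423,425,Skeletal def.,,,
435,,,Skeletal def.,,,
445,,448,,,,
453,,,Benzene ring def.,Trp,454,B57
492,,,COO- bend. + CH2,Gly,"497, 496","B58, B59"
,502,,,,,
537,538,543,COO- def.,Arg,535,B60
572,,,COO- rock.,Thr,568,B61
591,,,NH def.,Trp,595,B62
630,628,630,C-S str.,Met,632,B63
652,649,650,Imidazole ring breathing,His,657,B59
683,,,C-S str.,Met-Leu,685,B64
766,766,765,CH2 rock.,Met,765,B59
833,835,833,Ring breathing mode and out-of-plane,Tyr,837,B65
857,859,859,Ring def. Fermi resonance,,857,B65
885,885,886,C-N str. + Cb-Cd str.,Ala,885,B66
905,906,902,,Asp,902,B59
945,940,941,C-C str.,His,948,B57
954,950,953,C-C str.,Gly(Gly-Glu),956,B67
963,963,966,C-C str.,Pro-Leu,961,B67
1011,1010,1010,Indole asym. ring breathing,Trp(Trp-Leu),1011,B67
1041,1043,1037,C-N str.,Pro(Pro-Leu),1044,B67
1053,1052,1051,"Ca-N str., C-N str.","Met-Leu, Ala-Ala","1056, 1050","B63, B67"
1069,,,C-N str.,Glu(Gly-Glu),1066,B67
1095,,,"Ca-C-N str. asym., NH2 twist.","Pro-Pro, Met-Leu","1092, 1095","B63, B68"
1130,1132,1132,N-H wag.,Lys,1142,B61
1169,1174,1173,N-H wag.,His,1160,B61
,1183,1183,,"Glu-Gly, Leu-Gly","1194, 1174",B67
1212,1215,1213,Ring def.,Phe,1214,B59
1241,1240,1243,CH2 wag.,Leu(Leu-Gly),1241,B67
1260,1262,1256,Amide III,,1264,B61
,1270,1270,CH2 wag.,"Leu(Leu-Glu), Ser-Gly","1276, 1266",B67
1283,1279,,CH2 wag.,Trp(Trp-Leu),1283,B67
1307,1307,1307,CH2 wag.,Glu(Gly-Glu),1307,B67
1324,1326,1327,C-NH2 str.,Met-Leu,1323,B67
1339,1333,1335,C-H bend.,Asp,1336,B69
1348,1346,1344,,Glu,1346,B59
1366,1366,1367,Indole vibration,Trp(Trp-Leu),1363,B67
1385,1385,1386,,,,
1392,1394,1396,COO- sym. str.,Leu-Leu,1396,B67
1441,,,CH2 sciss.,Gly(Leu-Gly),1440,B67
1459,1453,1457,CH2 sciss.,Gly(Leu-Gly),1454,B61
1473,1467,1468,"Cg, Cd bend.",Arg,1477,B59
1557,1555,1555,Cb-Cg def.,Lys,1556,B70
1605,1600,,Ring C-C str.,Phe,1602,B61
,1613,1611,Sym.ring C-C str.,Gly(Tyr-Gly),1613,B67
1618,,1623,Indole NH,Trp(Trp-Leu),1621,B61
1663,1666,1664,Amide I,,1664,B61
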