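experiment_id,lab,injection,perfusion,muscle,titre,mns,double_mns,ipsi_dorsal_median_um,ipsi_premotor_ins,contra_premotor_ins,total_premotor_ins,sampling
170427 n2,UCL,P2,P11,LG,1×10^10,46,3,285,741,116,857,1/2 (30 μm)
170427 n2,UCL,P2,P11,TA,5×10^9,41,,298,912,88,1000,1/2 (30 μm)
170427 n3,UCL,P2,P11,LG,1×10^10,32,2,267,620,87,707,1/2 (30 μm)
170427 n3,UCL,P2,P11,TA,5×10^9,6,,276,386,34,420,1/2 (30 μm)
170503 n6,UCL,P2,P11,LG,1×10^10,83,1,294,1935,639,2574,1/2 (30 μm)
170503 n6,UCL,P2,P11,TA,5×10^9,55,,315,1887,315,2202,1/2 (30 μm)
170125 n3,UCL,P1,P10,LG,5×10^9,39,0,365,670,107,777,1/2 (30 μm)
170125 n3,UCL,P1,P10,MG,5×10^9,39,,353,819,307,1126,1/2 (30 μm)
170508 n7,UCL,P2,P11,LG,1×10^10,110,3,352,1955,382,2337,1/2 (30 μm)
170508 n7,UCL,P2,P11,MG,5×10^9,67,,322,1497,429,1926,1/2 (30 μm)
170125 n7,UCL,P1,P10,TA,5×10^9,47,0,363,907,308,1215,1/2 (30 μm)
170125 n7,UCL,P1,P10,PL,5×10^9,39,,380,1044,195,1239,1/2 (30 μm)
170125 n8,UCL,P1,P10,TA,5×10^9,22,2,343,920,157,1077,1/2 (30 μm)
170125 n8,UCL,P1,P10,PL,5×10^9,22,,330,741,83,824,1/2 (30 μm)
1570,UoG,P1,P10,LG,2×10^8,11,-,322,1111,404,1515,1/8 (60 μm)
1571,UoG,P1,P10,LG,2×10^8,12,-,340,760,196,956,1/8 (60 μm)
1573,UoG,P1,P10,TA,5×10^8,10,-,332,447,68,515,1/8 (60 μm)
1574,UoG,P1,P10,TA,5×10^8,14,-,365,297,26,323,1/8 (60 μm)
1577,UoG,P2,P10,LG,2×10^9,18,2,329,313,43,356,1/8 (60 μm)
1577,UoG,P2,P10,TA,5×10^9,26,,312,688,105,793,1/8 (60 μm)
1578,UoG,P2,P10,LG,2×10^9,21,5,330,292,34,326,1/8 (60 μm)
1578,UoG,P2,P10,TA,5×10^9,22,,346,790,130,920,1/8 (60 μm)
1579,UoG,P2,P10,LG,2×10^9,30,1,322,1023,194,1217,1/8 (60 μm)
1579,UoG,P2,P10,MG,5×10^8,7,,306,169,19,188,1/8 (60 μm)
1580,UoG,P2,P10,LG,2×10^9,14,0,316,414,48,462,1/8 (60 μm)
1580,UoG,P2,P10,MG,5×10^8,8,,348,470,87,557,1/8 (60 μm)
1605,UoG,P1,P10,MG,1×10^8,6,-,340,412,110,522,1/8 (60 μm)
1611,UoG,P1,P10,PL,1×10^8,2,-,328,167,24,191,1/8 (60 μm)
1613,UoG,P2,P10,PL,1×10^8,1,-,340,164,16,180,1/8 (60 μm)
1639,UoG,P2,P10,TA,2×10^8,15,-,341,591,94,685,1/8 (60 μm)
1640,UoG,P2,P10,PL,2×10^8,20,-,322,629,122,751,1/8 (60 μm)
1644,UoG,P2,P10,LG,1×10^8,1,-,344,142,32,174,1/8 (60 μm)
1644,UoG,P2,P10,TA,2×10^8,-,,296,57,11,68,1/8 (60 μm)
1646,UoG,P2,P10,LG,1×10^8,1,-,261,90,16,106,1/8 (60 μm)
1646,UoG,P2,P10,TA,2×10^8,3,,305,76,13,89,1/8 (60 μm)
1653,UoG,P2,P10,LG,1×10^8,2,-,307,60,6,66,1/8 (60 μm)
1653,UoG,P2,P10,TA,2×10^8,2,,312,58,8,66,1/8 (60 μm)
1656,UoG,P2,P10,LG,1×10^8,-,-,311,563,145,708,1/8 (60 μm)
1657,UoG,P2,P10,LG,1×10^8,1,-,321,323,51,374,1/8 (60 μm)
1660,UoG,P2,P10,MG,2×10^8,7,-,324,509,3,512,1/8 (60 μm)
1661,UoG,P2,P10,MG,2×10^8,10,-,338,175,63,238,1/8 (60 μm)
1662,UoG,P2,P10,MG,2×10^8,10,-,313,375,230,605,1/8 (60 μm)
1701,UoG,P2,P10,LG,2×10^9,8,2,351,169,26,195,1/8 (60 μm)
1701,UoG,P2,P10,MG,5×10^9,34,,329,594,190,784,1/8 (60 μm)
1702,UoG,P2,P10,LG,2×10^9,14,2,331,561,107,668,1/8 (60 μm)
1702,UoG,P2,P10,MG,5×10^9,2,,322,76,11,87,1/8 (60 μm)
353,MDC,P4,P10,GS,1×10^9,31,-,283,1542,431,1973,All (40 μm)
399,MDC,P4,P10,GS,1×10^9,41,-,286,569,77,646,All (40 μm)
1332,MDC,P4,P10,GS,1×10^9,18,-,317,1605,323,1928,All (40 μm)
1349,MDC,P4,P10,GS,1×10^9,18,-,305,1416,459,1875,All (40 μm)
700,MDC,P4,P10,TA,1×10^9,47,-,318,1723,122,1845,All (40 μm)
721,MDC,P4,P10,TA,1×10^9,22,-,310,1934,465,2399,All (40 μm)
1324,MDC,P4,P10,TA,1×10^9,17,-,292,2041,301,2342,All (40 μm)
1,Salk,P2,P10,GS,1×10^11,N/A,N/A,328,9185,2735,11920,All (60 μm)
1,Salk,P2,P10,TA,1×10^11,N/A,N/A,349,3330,731,4061,All (60 μm)
2,Salk,P2,P10,GS,1×10^11,N/A,N/A,303,8827,3867,12694,All (60 μm)
2,Salk,P2,P10,TA,1×10^11,N/A,N/A,294,3198,1132,4330,All (60 μm)
a,Salk,P1,P8,GS,1×10^10,N/A,N/A,248,334,42,376,1/9 (30 μm)
b,Salk,P1,P8,GS,1×10^10,N/A,N/A,237,275,30,305,1/9 (30 μm)
22 a_4,Salk,P2,P9,GS,3×10^11,N/A,N/A,403,464,58,522,All (60 μm)
26 a_1,Salk,P2,P9,GS,3×10^11,N/A,N/A,383,941,91,1032,All (60 μm)
26 a_2,Salk,P2,P9,GS,3×10^11,N/A,N/A,351,1910,401,2311,All (60 μm)
26 a_4,Salk,P2,P9,GS,3×10^11,N/A,N/A,382,1923,392,2315,All (60 μm)
26_1,Salk,P2,P9,TA,3×10^11,N/A,N/A,348,3236,263,3499,All (60 μm)
26_3,Salk,P2,P9,TA,3×10^11,N/A,N/A,367,2078,465,2543,All (60 μm)
26_4,Salk,P2,P9,TA,3×10^11,N/A,N/A,350,2494,597,3091,All (60 μm)
1_1PRV,Salk,P11,P13,GS,1×10^9,N/A,N/A,318,430,54,484,1/4 (60 μm)
1_4PRV,Salk,P11,P13,GS,1×10^9,N/A,N/A,349,238,23,261,1/4 (60 μm)
2_2PRV,Salk,P11,P13,GS,1×10^9,N/A,N/A,357,515,82,597,1/4 (60 μm)
3_3PRV,Salk,P11,P13,GS,1×10^9,N/A,N/A,377,1005,53,1058,1/4 (60 μm)
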