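t_ms,x_px,y_px,valid
0.0,0.0,0.0,0
15.3846,0.0,0.0,0
30.7692,0.0,0.0,0
46.1538,0.0,0.0,0
61.5385,0.0,0.0,0
76.9231,0.0,0.0,0
92.3077,0.0,0.0,0
107.6923,0.0,0.0,0
123.0769,0.0,0.0,0
138.4615,0.0,0.0,0
153.8462,0.0,0.0,0
169.2308,0.0,0.0,0
184.6154,1296.69,685.24,1
200.0,1261.76,732.89,1
215.3846,1324.6,712.1,1
230.7692,0.0,0.0,0
246.1538,0.0,0.0,0
261.5385,1290.06,671.21,1
276.9231,0.0,0.0,0
292.3077,0.0,0.0,0
307.6923,0.0,0.0,0
323.0769,0.0,0.0,0
338.4615,0.0,0.0,0
353.8462,0.0,0.0,0
369.2308,0.0,0.0,0
384.6154,0.0,0.0,0
400.0,0.0,0.0,0
415.3846,1279.37,724.03,1
430.7692,1319.46,717.33,1
446.1538,0.0,0.0,0
461.5385,0.0,0.0,0
476.9231,0.0,0.0,0
492.3077,0.0,0.0,0
507.6923,1263.62,718.18,1
523.0769,0.0,0.0,0
538.4615,1271.54,739.19,1
553.8462,1287.24,745.93,1
569.2308,0.0,0.0,0
584.6154,0.0,0.0,0
600.0,0.0,0.0,0
615.3846,0.0,0.0,0
630.7692,0.0,0.0,0
646.1538,0.0,0.0,0
661.5385,0.0,0.0,0
676.9231,0.0,0.0,0
692.3077,0.0,0.0,0
707.6923,0.0,0.0,0
723.0769,0.0,0.0,0
738.4615,0.0,0.0,0
753.8462,0.0,0.0,0
769.2308,1558.36,686.28,1
784.6154,0.0,0.0,0
800.0,0.0,0.0,0
815.3846,0.0,0.0,0
830.7692,0.0,0.0,0
846.1538,0.0,0.0,0
861.5385,1548.85,731.02,1
876.9231,0.0,0.0,0
892.3077,0.0,0.0,0
907.6923,1618.38,742.11,1
923.0769,1579.94,716.49,1
938.4615,0.0,0.0,0
953.8462,0.0,0.0,0
969.2308,1591.08,747.83,1
984.6154,1585.78,714.78,1
1000.0,1587.08,731.76,1
1015.3846,1618.4,686.51,1
1030.7692,0.0,0.0,0
1046.1538,0.0,0.0,0
1061.5385,0.0,0.0,0
1076.9231,0.0,0.0,0
1092.3077,0.0,0.0,0
1107.6923,0.0,0.0,0
1123.0769,1600.89,679.46,1
1138.4615,0.0,0.0,0
1153.8462,1585.56,696.76,1
1169.2308,0.0,0.0,0
1184.6154,1636.12,712.37,1
1200.0,1588.9,651.22,1
1215.3846,1589.47,720.57,1
1230.7692,0.0,0.0,0
1246.1538,0.0,0.0,0
1261.5385,1606.57,730.55,1
1276.9231,1571.38,722.02,1
1292.3077,0.0,0.0,0
1307.6923,0.0,0.0,0
1323.0769,0.0,0.0,0
1338.4615,0.0,0.0,0
1353.8462,0.0,0.0,0
1369.2308,1585.78,726.12,1
1384.6154,0.0,0.0,0
1400.0,0.0,0.0,0
1415.3846,1585.16,699.14,1
1430.7692,1593.97,703.23,1
1446.1538,0.0,0.0,0
1461.5385,1580.62,729.33,1
1476.9231,0.0,0.0,0
1492.3077,1594.25,687.11,1
1507.6923,1552.04,723.7,1
1523.0769,0.0,0.0,0
1538.4615,1609.11,719.33,1
1553.8462,0.0,0.0,0
1569.2308,1588.73,717.18,1
1584.6154,0.0,0.0,0
1600.0,1590.73,710.73,1
1615.3846,0.0,0.0,0
1630.7692,1586.89,665.55,1
1646.1538,0.0,0.0,0
1661.5385,0.0,0.0,0
1676.9231,0.0,0.0,0
1692.3077,0.0,0.0,0
1707.6923,0.0,0.0,0
1723.0769,1604.61,723.31,1
1738.4615,0.0,0.0,0
1753.8462,1624.43,744.63,1
1769.2308,0.0,0.0,0
1784.6154,0.0,0.0,0
1800.0,1594.25,710.36,1
1815.3846,1596.81,696.62,1
1830.7692,1624.75,708.46,1
1846.1538,0.0,0.0,0
1861.5385,1613.68,728.61,1
1876.9231,1624.56,737.69,1
1892.3077,0.0,0.0,0
1907.6923,1615.65,723.22,1
1923.0769,1572.91,739.11,1
1938.4615,0.0,0.0,0
1953.8462,0.0,0.0,0
1969.2308,0.0,0.0,0
1984.6154,1587.37,707.05,1
2000.0,1614.74,687.51,1
2015.3846,1567.51,745.13,1
2030.7692,1602.67,718.99,1
2046.1538,0.0,0.0,0
2061.5385,0.0,0.0,0
2076.9231,0.0,0.0,0
2092.3077,0.0,0.0,0
2107.6923,0.0,0.0,0
2123.0769,0.0,0.0,0
2138.4615,1578.48,667.83,1
2153.8462,0.0,0.0,0
2169.2308,0.0,0.0,0
2184.6154,1599.58,713.05,1
2200.0,0.0,0.0,0
2215.3846,0.0,0.0,0
2230.7692,0.0,0.0,0
2246.1538,0.0,0.0,0
2261.5385,1638.83,678.17,1
2276.9231,1591.63,738.79,1
2292.3077,1614.24,692.87,1
2307.6923,0.0,0.0,0
2323.0769,1588.98,702.34,1
2338.4615,1600.15,724.6,1
2353.8462,1584.87,735.55,1
2369.2308,0.0,0.0,0
2384.6154,1589.96,758.92,1
2400.0,1596.01,722.93,1
2415.3846,0.0,0.0,0
2430.7692,0.0,0.0,0
2446.1538,1605.68,757.06,1
2461.5385,0.0,0.0,0
2476.9231,0.0,0.0,0
2492.3077,0.0,0.0,0
2507.6923,0.0,0.0,0
2523.0769,0.0,0.0,0
2538.4615,0.0,0.0,0
2553.8462,1621.09,748.64,1
2569.2308,0.0,0.0,0
2584.6154,0.0,0.0,0
2600.0,0.0,0.0,0
2615.3846,1596.7,742.83,1
2630.7692,0.0,0.0,0
2646.1538,0.0,0.0,0
2661.5385,1577.49,703.27,1
2676.9231,1591.99,738.55,1
2692.3077,0.0,0.0,0
2707.6923,0.0,0.0,0
2723.0769,0.0,0.0,0
2738.4615,0.0,0.0,0
2753.8462,0.0,0.0,0
2769.2308,0.0,0.0,0
2784.6154,1551.03,681.75,1
2800.0,0.0,0.0,0
2815.3846,0.0,0.0,0
2830.7692,0.0,0.0,0
2846.1538,1613.12,739.5,1
2861.5385,1601.81,697.38,1
2876.9231,0.0,0.0,0
2892.3077,1583.44,732.93,1
2907.6923,0.0,0.0,0
2923.0769,0.0,0.0,0
2938.4615,0.0,0.0,0
2953.8462,1639.62,773.72,1
2969.2308,0.0,0.0,0
2984.6154,1630.52,730.55,1
3000.0,0.0,0.0,0
3015.3846,0.0,0.0,0
3030.7692,1578.76,757.06,1
3046.1538,1572.26,717.08,1
3061.5385,1574.25,700.88,1
3076.9231,0.0,0.0,0
3092.3077,1593.36,691.6,1
3107.6923,0.0,0.0,0
3123.0769,0.0,0.0,0
3138.4615,0.0,0.0,0
3153.8462,1607.02,711.89,1
3169.2308,1584.63,705.26,1
3184.6154,1590.11,739.08,1
3200.0,0.0,0.0,0
3215.3846,1548.43,740.87,1
3230.7692,0.0,0.0,0
3246.1538,0.0,0.0,0
3261.5385,0.0,0.0,0
3276.9231,0.0,0.0,0
3292.3077,1579.67,730.26,1
3307.6923,0.0,0.0,0
3323.0769,1591.11,740.65,1
3338.4615,1588.84,699.41,1
3353.8462,1577.09,742.32,1
3369.2308,0.0,0.0,0
3384.6154,0.0,0.0,0
3400.0,0.0,0.0,0
3415.3846,0.0,0.0,0
3430.7692,0.0,0.0,0
3446.1538,0.0,0.0,0
3461.5385,1574.61,704.77,1
3476.9231,0.0,0.0,0
3492.3077,0.0,0.0,0
3507.6923,0.0,0.0,0
3523.0769,0.0,0.0,0
3538.4615,0.0,0.0,0
3553.8462,0.0,0.0,0
3569.2308,0.0,0.0,0
3584.6154,0.0,0.0,0
3600.0,1554.93,711.68,1
3615.3846,0.0,0.0,0
3630.7692,0.0,0.0,0
3646.1538,0.0,0.0,0
3661.5385,0.0,0.0,0
3676.9231,0.0,0.0,0
3692.3077,0.0,0.0,0
3707.6923,0.0,0.0,0
3723.0769,0.0,0.0,0
3738.4615,1633.38,750.95,1
3753.8462,1601.36,712.64,1
3769.2308,0.0,0.0,0
3784.6154,0.0,0.0,0
3800.0,0.0,0.0,0
3815.3846,0.0,0.0,0
3830.7692,0.0,0.0,0
3846.1538,1598.14,717.83,1
3861.5385,0.0,0.0,0
3876.9231,0.0,0.0,0
3892.3077,1582.2,699.73,1
3907.6923,0.0,0.0,0
3923.0769,1569.01,732.43,1
3938.4615,0.0,0.0,0
3953.8462,1583.69,702.06,1
3969.2308,0.0,0.0,0
3984.6154,0.0,0.0,0
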