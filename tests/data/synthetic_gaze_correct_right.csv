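t_ms,x_px,y_px,valid
0.0,1234.37,718.6,1
15.3846,1293.53,725.12,1
30.7692,1296.69,690.93,1
46.1538,1273.06,727.7,1
61.5385,1288.24,725.46,1
76.9231,1318.36,719.42,1
92.3077,1303.79,760.77,1
107.6923,1295.87,744.04,1
123.0769,1295.42,687.79,1
138.4615,1260.63,708.42,1
153.8462,1301.62,718.11,1
169.2308,1243.03,695.75,1
184.6154,1272.55,724.04,1
200.0,1270.19,725.59,1
215.3846,1241.23,726.79,1
230.7692,1277.53,759.83,1
246.1538,1316.86,698.94,1
261.5385,1272.37,724.24,1
276.9231,1252.92,722.11,1
292.3077,1277.96,727.5,1
307.6923,1299.15,734.24,1
323.0769,1284.33,770.67,1
338.4615,1279.94,716.61,1
353.8462,1248.4,671.08,1
369.2308,1291.24,697.84,1
384.6154,1290.89,726.46,1
400.0,1626.1,740.74,1
415.3846,1629.48,719.42,1
430.7692,1611.21,711.68,1
446.1538,1558.2,722.7,1
461.5385,1562.9,701.3,1
476.9231,1570.56,741.38,1
492.3077,1602.24,696.06,1
507.6923,1577.62,716.52,1
523.0769,1625.38,732.32,1
538.4615,1601.08,726.36,1
553.8462,1603.83,712.21,1
569.2308,1612.62,702.91,1
584.6154,1603.27,718.38,1
600.0,1563.46,706.95,1
615.3846,1651.49,666.09,1
630.7692,1628.88,756.76,1
646.1538,1630.25,764.98,1
661.5385,1578.52,718.01,1
676.9231,1553.55,741.7,1
692.3077,1561.28,717.47,1
707.6923,1571.57,756.12,1
723.0769,1615.62,717.02,1
738.4615,1616.04,690.6,1
753.8462,1628.78,695.14,1
769.2308,1644.41,744.62,1
784.6154,1607.39,726.94,1
800.0,1603.6,700.15,1
815.3846,1587.26,679.08,1
830.7692,1587.87,741.37,1
846.1538,1569.2,739.15,1
861.5385,1607.16,694.94,1
876.9231,1602.77,728.06,1
892.3077,1586.3,743.03,1
907.6923,1577.09,696.43,1
923.0769,1605.93,757.68,1
938.4615,1625.3,735.34,1
953.8462,1597.38,698.33,1
969.2308,1601.99,734.09,1
984.6154,1583.05,702.87,1
1000.0,1589.87,747.51,1
1015.3846,1588.32,702.61,1
1030.7692,1589.04,709.41,1
1046.1538,1581.94,683.65,1
1061.5385,1604.55,725.51,1
1076.9231,1625.15,727.91,1
1092.3077,1573.98,722.15,1
1107.6923,1627.42,696.51,1
1123.0769,1586.35,736.65,1
1138.4615,1587.17,723.19,1
1153.8462,1546.54,676.27,1
1169.2308,1540.54,702.5,1
1184.6154,1612.28,703.76,1
1200.0,1570.72,731.69,1
1215.3846,1613.87,700.69,1
1230.7692,1596.68,746.12,1
1246.1538,1601.23,753.46,1
1261.5385,1625.92,741.13,1
1276.9231,1593.88,688.21,1
1292.3077,1521.42,716.25,1
1307.6923,1556.02,740.95,1
1323.0769,1617.69,728.03,1
1338.4615,1641.08,709.89,1
1353.8462,1593.34,693.5,1
1369.2308,1579.55,756.63,1
1384.6154,1563.88,690.02,1
1400.0,1607.96,699.11,1
1415.3846,1554.67,735.64,1
1430.7692,1567.2,728.96,1
1446.1538,1598.62,709.0,1
1461.5385,1597.84,726.43,1
1476.9231,1589.63,716.92,1
1492.3077,1619.76,743.77,1
1507.6923,1567.26,760.88,1
1523.0769,1568.45,665.53,1
1538.4615,1586.01,716.17,1
1553.8462,1597.01,714.97,1
1569.2308,1587.84,708.59,1
1584.6154,1640.99,690.05,1
1600.0,1581.79,699.17,1
1615.3846,1610.0,743.06,1
1630.7692,1582.18,722.53,1
1646.1538,1602.83,718.45,1
1661.5385,1585.45,702.92,1
1676.9231,0.0,0.0,0
1692.3077,1632.55,711.45,1
1707.6923,1587.85,714.95,1
1723.0769,1634.69,689.06,1
1738.4615,1578.7,778.52,1
1753.8462,1584.86,718.22,1
1769.2308,1620.81,712.39,1
1784.6154,1539.22,704.87,1
1800.0,1557.49,720.19,1
1815.3846,1595.93,738.58,1
1830.7692,1606.39,704.99,1
1846.1538,1608.57,711.73,1
1861.5385,1588.11,738.86,1
1876.9231,1562.67,750.53,1
1892.3077,1614.54,707.49,1
1907.6923,1605.69,739.45,1
1923.0769,1569.57,705.43,1
1938.4615,1597.49,686.01,1
1953.8462,1637.07,715.38,1
1969.2308,1598.34,714.87,1
1984.6154,1568.17,717.19,1
2000.0,1585.67,688.92,1
2015.3846,1587.01,688.54,1
2030.7692,1603.35,718.11,1
2046.1538,1616.34,703.35,1
2061.5385,1573.92,718.99,1
2076.9231,1580.44,731.14,1
2092.3077,1619.01,702.77,1
2107.6923,1612.55,721.99,1
2123.0769,1626.82,739.06,1
2138.4615,1561.75,753.6,1
2153.8462,1573.36,697.75,1
2169.2308,1618.71,741.62,1
2184.6154,1573.49,744.91,1
2200.0,1602.95,725.91,1
2215.3846,1594.19,703.42,1
2230.7692,1578.18,758.74,1
2246.1538,1629.43,705.72,1
2261.5385,1595.1,711.22,1
2276.9231,1583.71,747.27,1
2292.3077,1591.74,745.55,1
2307.6923,1601.19,723.91,1
2323.0769,1559.03,676.63,1
2338.4615,1575.46,725.62,1
2353.8462,1565.83,695.64,1
2369.2308,1546.82,698.84,1
2384.6154,1618.1,755.6,1
2400.0,1628.71,720.03,1
2415.3846,1623.02,697.86,1
2430.7692,1554.5,731.15,1
2446.1538,1604.68,692.6,1
2461.5385,1611.18,744.16,1
2476.9231,1582.24,752.95,1
2492.3077,1614.37,729.83,1
2507.6923,1569.62,705.23,1
2523.0769,1570.58,728.6,1
2538.4615,1576.15,699.26,1
2553.8462,1578.74,754.56,1
2569.2308,1572.11,732.96,1
2584.6154,1617.68,689.22,1
2600.0,1570.68,774.98,1
2615.3846,1584.67,712.96,1
2630.7692,1580.69,739.85,1
2646.1538,1646.4,736.59,1
2661.5385,1574.67,727.23,1
2676.9231,1606.32,752.86,1
2692.3077,1637.5,699.09,1
2707.6923,1568.11,706.82,1
2723.0769,1576.23,692.54,1
2738.4615,1587.8,716.21,1
2753.8462,1564.9,741.08,1
2769.2308,1623.71,705.35,1
2784.6154,1584.48,749.93,1
2800.0,1619.69,740.46,1
2815.3846,1607.7,672.8,1
2830.7692,1595.93,695.74,1
2846.1538,1617.5,709.93,1
2861.5385,1588.47,686.58,1
2876.9231,1619.71,726.36,1
2892.3077,1565.34,706.66,1
2907.6923,1578.36,738.08,1
2923.0769,1623.19,727.3,1
2938.4615,1547.47,717.83,1
2953.8462,1606.37,686.23,1
2969.2308,1586.04,735.44,1
2984.6154,1582.96,696.04,1
3000.0,1579.49,719.98,1
3015.3846,1624.95,759.29,1
3030.7692,1560.57,763.14,1
3046.1538,1614.55,735.42,1
3061.5385,1606.39,695.63,1
3076.9231,1585.75,713.95,1
3092.3077,1593.5,678.86,1
3107.6923,1611.63,715.67,1
3123.0769,1581.92,687.86,1
3138.4615,1560.94,714.1,1
3153.8462,1601.95,740.24,1
3169.2308,1576.27,703.65,1
3184.6154,1586.13,736.47,1
3200.0,1596.72,751.49,1
3215.3846,1612.32,736.64,1
3230.7692,1636.96,728.49,1
3246.1538,1603.32,714.09,1
3261.5385,1598.14,700.54,1
3276.9231,1614.2,705.99,1
3292.3077,1602.03,672.62,1
3307.6923,1557.09,763.77,1
3323.0769,1581.81,723.73,1
3338.4615,1567.34,661.42,1
3353.8462,1611.39,726.67,1
3369.2308,1624.55,747.96,1
3384.6154,1603.64,736.61,1
3400.0,1572.07,741.44,1
3415.3846,1613.78,730.7,1
3430.7692,1573.61,680.61,1
3446.1538,1601.29,751.04,1
3461.5385,1568.25,735.22,1
3476.9231,1563.99,687.61,1
3492.3077,1563.6,712.85,1
3507.6923,1595.92,712.1,1
3523.0769,1580.47,728.01,1
3538.4615,1605.46,698.29,1
3553.8462,1565.99,742.43,1
3569.2308,1606.69,697.94,1
3584.6154,1581.44,716.73,1
3600.0,1624.08,723.72,1
3615.3846,1618.76,731.54,1
3630.7692,1590.6,698.06,1
3646.1538,1597.99,711.86,1
3661.5385,1601.07,728.29,1
3676.9231,1606.09,716.78,1
3692.3077,1589.28,743.08,1
3707.6923,1620.49,690.61,1
3723.0769,1583.96,688.28,1
3738.4615,1551.79,693.84,1
3753.8462,1601.13,712.84,1
3769.2308,1593.06,707.83,1
3784.6154,1614.49,749.92,1
3800.0,1609.1,727.57,1
3815.3846,1598.47,724.78,1
3830.7692,1597.97,722.26,1
3846.1538,1598.41,705.05,1
3861.5385,1580.53,729.16,1
3876.9231,1567.85,735.87,1
3892.3077,1576.85,692.2,1
3907.6923,1593.45,726.27,1
3923.0769,1544.08,733.73,1
3938.4615,1585.61,764.63,1
3953.8462,1573.19,750.0,1
3969.2308,1593.52,724.52,1
3984.6154,1577.02,713.26,1
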