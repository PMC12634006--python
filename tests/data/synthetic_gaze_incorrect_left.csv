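t_ms,x_px,y_px,valid
0.0,1832.29,879.07,1
15.3846,1801.49,878.72,1
30.7692,1820.55,845.05,1
46.1538,1817.86,845.91,1
61.5385,1809.3,843.67,1
76.9231,1742.89,810.88,1
92.3077,1810.33,792.92,1
107.6923,1812.07,782.39,1
123.0769,1780.24,764.47,1
138.4615,1805.88,726.69,1
153.8462,1812.26,751.65,1
169.2308,1738.39,685.68,1
184.6154,1808.87,703.49,1
200.0,1771.85,676.69,1
215.3846,1753.32,629.44,1
230.7692,1781.68,620.21,1
246.1538,1756.08,665.81,1
261.5385,1760.76,600.77,1
276.9231,1745.05,561.82,1
292.3077,1750.35,597.26,1
307.6923,1734.77,569.76,1
323.0769,1747.02,512.75,1
338.4615,1732.44,555.58,1
353.8462,1723.65,470.56,1
369.2308,1779.08,524.01,1
384.6154,1751.62,493.74,1
400.0,1758.59,473.52,1
415.3846,1787.39,454.5,1
430.7692,0.0,0.0,0
446.1538,1741.13,402.08,1
461.5385,1714.54,425.89,1
476.9231,1759.76,443.14,1
492.3077,1752.08,502.87,1
507.6923,1765.45,498.88,1
523.0769,1737.52,478.22,1
538.4615,1731.67,547.82,1
553.8462,1690.5,507.34,1
569.2308,1753.55,561.06,1
584.6154,1703.25,598.32,1
600.0,1728.01,575.6,1
615.3846,1751.43,594.36,1
630.7692,1741.08,644.32,1
646.1538,1737.02,660.22,1
661.5385,1749.87,684.68,1
676.9231,1696.69,697.46,1
692.3077,1740.12,753.37,1
707.6923,1769.08,734.79,1
723.0769,1766.56,708.87,1
738.4615,1702.88,766.86,1
753.8462,1761.27,764.7,1
769.2308,1748.95,772.75,1
784.6154,1714.84,805.64,1
800.0,1705.8,838.27,1
815.3846,1734.67,857.64,1
830.7692,0.0,0.0,0
846.1538,1749.59,874.17,1
861.5385,1715.33,908.03,1
876.9231,1740.4,900.58,1
892.3077,1763.0,895.37,1
907.6923,1722.97,911.67,1
923.0769,1701.38,943.09,1
938.4615,1710.78,890.83,1
953.8462,1637.57,890.7,1
969.2308,1684.87,883.13,1
984.6154,1629.47,878.35,1
1000.0,1647.17,855.46,1
1015.3846,1645.15,764.9,1
1030.7692,1620.71,754.71,1
1046.1538,1593.85,773.15,1
1061.5385,1589.94,820.79,1
1076.9231,1605.7,784.31,1
1092.3077,1542.21,751.58,1
1107.6923,1540.49,771.11,1
1123.0769,1556.53,737.42,1
1138.4615,1555.33,714.11,1
1153.8462,1523.81,691.88,1
1169.2308,1499.34,704.64,1
1184.6154,1515.78,694.93,1
1200.0,1477.82,695.71,1
1215.3846,1522.51,685.75,1
1230.7692,1493.28,662.97,1
1246.1538,1493.88,656.56,1
1261.5385,1415.23,624.12,1
1276.9231,1413.98,622.36,1
1292.3077,1406.44,622.42,1
1307.6923,1371.48,571.81,1
1323.0769,1375.86,600.39,1
1338.4615,1397.91,567.13,1
1353.8462,1364.51,582.03,1
1369.2308,1393.47,619.11,1
1384.6154,1447.48,618.7,1
1400.0,1432.01,625.65,1
1415.3846,1448.86,656.35,1
1430.7692,1449.75,685.79,1
1446.1538,1446.93,609.61,1
1461.5385,1465.35,695.83,1
1476.9231,1492.35,701.22,1
1492.3077,1484.8,712.38,1
1507.6923,1511.9,719.43,1
1523.0769,1512.57,712.36,1
1538.4615,1533.42,726.18,1
1553.8462,1584.56,769.97,1
1569.2308,1574.66,761.32,1
1584.6154,1541.95,766.77,1
1600.0,1580.47,798.57,1
1615.3846,1640.79,781.78,1
1630.7692,1652.77,813.43,1
1646.1538,1594.67,811.18,1
1661.5385,1645.07,867.3,1
1676.9231,1647.27,816.75,1
1692.3077,1600.03,872.55,1
1707.6923,1679.12,903.68,1
1723.0769,1732.17,913.55,1
1738.4615,1680.08,923.37,1
1753.8462,1702.45,911.18,1
1769.2308,1745.06,981.77,1
1784.6154,1724.11,965.12,1
1800.0,1712.43,920.5,1
1815.3846,1718.09,919.06,1
1830.7692,1665.45,972.91,1
1846.1538,1699.86,947.12,1
1861.5385,1645.11,947.09,1
1876.9231,1666.05,959.18,1
1892.3077,1672.59,968.56,1
1907.6923,1680.82,939.22,1
1923.0769,1611.67,965.47,1
1938.4615,1623.95,956.74,1
1953.8462,1612.69,945.45,1
1969.2308,1552.91,986.54,1
1984.6154,1581.53,987.72,1
2000.0,1577.72,918.68,1
2015.3846,1573.64,993.76,1
2030.7692,1595.79,947.58,1
2046.1538,1540.52,948.2,1
2061.5385,1525.11,974.64,1
2076.9231,1513.05,985.98,1
2092.3077,1503.15,982.8,1
2107.6923,1503.3,999.76,1
2123.0769,1517.37,984.52,1
2138.4615,1444.81,991.91,1
2153.8462,1458.33,1001.05,1
2169.2308,1390.84,999.29,1
2184.6154,0.0,0.0,0
2200.0,1426.98,994.89,1
2215.3846,1362.89,1002.04,1
2230.7692,1408.13,956.09,1
2246.1538,1412.24,998.4,1
2261.5385,1344.36,982.66,1
2276.9231,1329.55,1015.1,1
2292.3077,1328.2,1017.77,1
2307.6923,1297.95,981.93,1
2323.0769,1290.6,969.8,1
2338.4615,1257.59,1057.74,1
2353.8462,1275.75,973.73,1
2369.2308,1244.82,970.2,1
2384.6154,1218.12,985.88,1
2400.0,1149.57,970.87,1
2415.3846,1167.24,1007.84,1
2430.7692,1166.39,974.18,1
2446.1538,1163.55,1006.77,1
2461.5385,1114.05,986.01,1
2476.9231,1125.11,987.98,1
2492.3077,1112.64,974.79,1
2507.6923,1060.99,1007.38,1
2523.0769,1073.61,969.82,1
2538.4615,1034.36,966.49,1
2553.8462,994.57,947.63,1
2569.2308,1001.04,985.27,1
2584.6154,1014.32,959.83,1
2600.0,974.73,984.56,1
2615.3846,947.73,957.07,1
2630.7692,948.45,981.73,1
2646.1538,927.22,990.13,1
2661.5385,896.78,978.07,1
2676.9231,830.22,928.47,1
2692.3077,0.0,0.0,0
2707.6923,865.45,944.92,1
2723.0769,956.99,935.74,1
2738.4615,949.55,921.49,1
2753.8462,912.04,954.99,1
2769.2308,981.28,869.07,1
2784.6154,945.3,926.05,1
2800.0,997.11,923.77,1
2815.3846,1028.91,892.51,1
2830.7692,1019.64,901.83,1
2846.1538,1055.69,864.95,1
2861.5385,1072.08,849.35,1
2876.9231,1027.91,862.85,1
2892.3077,1079.47,843.58,1
2907.6923,1107.12,852.48,1
2923.0769,1099.02,868.39,1
2938.4615,1094.31,850.43,1
2953.8462,1173.37,770.13,1
2969.2308,1160.66,808.52,1
2984.6154,1156.31,838.63,1
3000.0,1163.88,814.64,1
3015.3846,1197.82,800.43,1
3030.7692,1240.54,756.65,1
3046.1538,1217.51,762.4,1
3061.5385,0.0,0.0,0
3076.9231,1265.15,706.25,1
3092.3077,1268.28,726.6,1
3107.6923,1288.4,719.81,1
3123.0769,1304.43,696.12,1
3138.4615,1282.13,722.19,1
3153.8462,1271.77,708.61,1
3169.2308,1320.4,729.1,1
3184.6154,1337.8,664.36,1
3200.0,1318.92,690.64,1
3215.3846,1287.38,654.57,1
3230.7692,1307.8,596.67,1
3246.1538,1295.72,669.75,1
3261.5385,1276.98,640.47,1
3276.9231,1286.0,641.85,1
3292.3077,1296.57,634.13,1
3307.6923,1322.06,582.37,1
3323.0769,1285.0,623.92,1
3338.4615,1336.52,570.93,1
3353.8462,1312.27,565.22,1
3369.2308,1339.03,532.99,1
3384.6154,1334.98,585.99,1
3400.0,1317.72,563.83,1
3415.3846,1316.66,503.18,1
3430.7692,1321.64,555.97,1
3446.1538,1321.98,500.63,1
3461.5385,1331.91,468.7,1
3476.9231,1357.7,517.81,1
3492.3077,1331.38,497.07,1
3507.6923,1353.19,442.82,1
3523.0769,1339.71,480.8,1
3538.4615,1310.91,422.85,1
3553.8462,1330.78,404.45,1
3569.2308,1334.51,419.64,1
3584.6154,1356.05,437.36,1
3600.0,1344.24,451.44,1
3615.3846,1393.42,480.54,1
3630.7692,1372.12,462.27,1
3646.1538,1397.84,479.11,1
3661.5385,1432.78,510.25,1
3676.9231,1438.21,518.24,1
3692.3077,1431.58,571.0,1
3707.6923,1438.46,576.17,1
3723.0769,1472.02,617.8,1
3738.4615,1484.36,597.67,1
3753.8462,1564.85,580.03,1
3769.2308,1509.42,608.08,1
3784.6154,1517.41,640.44,1
3800.0,1615.99,652.59,1
3815.3846,1544.7,667.66,1
3830.7692,1585.69,649.81,1
3846.1538,1627.05,714.12,1
3861.5385,1632.71,675.7,1
3876.9231,1656.14,705.66,1
3892.3077,1701.18,765.29,1
3907.6923,1736.23,733.07,1
3923.0769,1704.26,745.05,1
3938.4615,0.0,0.0,0
3953.8462,1725.65,750.53,1
3969.2308,1737.15,823.38,1
3984.6154,1756.12,828.83,1
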