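# Published cost-overview table cells (euro), transcribed from the original
# study's scenario tables; obvious misprints normalized to plain decimal
# notation. One row per (scenario variation, x).
scenario,x,avg_fixed,avg_personnel,avg_maintenance,avg_variable,avg_total,primary_total,total
1.I,900,117.54,268.92,135.32,236.60,758.39,682549.10,1438366.20
1.I,1200,88.16,201.69,236.96,236.60,763.41,916090.16,1692946.20
1.I,1500,70.53,161.35,210.31,236.60,678.79,1018186.21,1789526.20
1.II,900,244.04,312.75,144.35,236.60,937.75,843971.58,1906916.20
1.II,1200,183.03,234.57,256.15,236.60,910.34,1092410.28,2178496.20
1.II,1500,146.42,187.65,226.71,236.60,797.39,1196083.18,2276076.20
1.III,900,58.77,268.92,222.56,236.60,786.85,708166.16,1689166.20
1.III,1200,50.38,201.69,206.76,236.60,695.43,834516.77,1793746.20
1.III,1500,44.08,161.35,212.42,236.60,654.45,981674.74,1940326.20
1.IV,900,173.08,272.64,163.10,242.43,851.25,766123.85,1524993.20
1.IV,1200,129.81,204.48,261.03,242.43,837.75,1005295.45,1781322.20
1.IV,1500,103.85,163.58,260.81,242.43,770.67,1155998.83,1933651.20
1.V,900,273.08,285.64,165.88,248.26,972.86,875572.68,1654740.20
1.V,1200,204.81,214.23,306.41,248.26,973.70,1168443.58,1971118.20
1.V,1500,163.85,171.38,265.33,248.26,848.82,1273235.98,2071496.20
2.I,900,125.71,322.78,135.32,236.60,820.42,738376.88,1605366.20
2.I,1200,94.29,242.09,236.96,236.60,809.93,971917.94,1859946.20
2.I,1500,75.43,193.67,210.31,236.60,716.01,1074013.99,1956526.20
2.II,900,240.77,372.93,144.35,236.60,994.65,895186.05,2060116.20
2.II,1200,180.58,279.70,256.15,236.60,953.02,1143624.75,2331696.20
2.II,1500,144.46,223.76,226.71,236.60,831.53,1247297.65,2429276.20
2.III,900,62.86,322.78,222.56,236.60,844.80,760316.66,1856166.20
2.III,1200,53.88,242.09,206.76,236.60,739.33,887192.61,1960746.20
2.III,1500,47.14,193.67,212.42,236.60,689.83,1034744.56,2107326.20
2.IV,900,181.25,326.50,163.10,242.43,913.28,821951.63,1691993.20
2.IV,1200,135.94,244.87,261.03,242.43,884.27,1061123.24,1948322.20
2.IV,1500,108.75,195.90,260.81,242.43,807.88,1211826.62,2100651.20
2.V,900,281.25,339.50,165.88,248.26,1034.89,931400.47,1821740.20
2.V,1200,210.94,254.62,306.41,248.26,1020.23,1224271.36,2138118.20
2.V,1500,168.75,203.70,265.33,248.26,886.04,1329063.76,2238496.20
3.I,900,110.92,268.92,218.81,236.60,835.26,751730.14,2291887.20
3.I,1200,85.71,201.69,226.38,236.60,750.39,900470.53,2442467.20
3.I,1500,69.84,161.35,233.71,236.60,701.50,1052254.28,2597047.20
3.II,900,222.54,312.75,236.32,236.60,1008.21,907387.74,2863437.20
3.II,1200,171.96,234.57,244.84,236.60,887.97,1065563.20,3021017.20
3.II,1500,140.12,187.65,252.85,236.60,817.22,1225825.19,3182597.20
3.III,900,62.86,268.92,188.81,236.60,757.20,681476.32,2376487.20
3.III,1200,53.88,201.69,199.45,236.60,691.62,829942.37,2531067.20
3.III,1500,47.14,161.35,192.31,236.60,637.41,956111.95,2641647.20
3.IV,900,166.46,272.64,302.62,242.43,984.14,885730.17,2442514.20
3.IV,1200,127.36,204.48,258.82,242.43,833.09,999711.38,2540843.20
3.IV,1500,103.16,163.58,259.24,242.43,768.41,1152617.82,2697172.20
3.V,900,266.46,285.64,311.75,248.26,1112.11,1000898.51,2562261.20
3.V,1200,202.36,214.23,265.95,248.26,930.81,1116969.00,2663639.20
3.V,1500,163.16,171.38,265.08,248.26,847.89,1271830.16,2822017.20
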