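peak_id,t_R_min,compound,formula,adduct,mz_observed,fragments,standard_confirmed,compound_class
P1,1.74,Citric acid/isocitric acid,C6H8O7,[M+H]+,193.0348,193.0346;175.0243;133.0137,0,organic acid
P2,7.34,Chlorogenic acid,C16H18O9,[M+H]+,355.0956,355.1034;163.0388,1,phenylpropanoid
P3,7.59,Unknown,,[M+H]+,506.2806,506.2872;327.2029;133.0869,0,unknown
P4,7.74,Cryptochlorogenic acid,C16H18O9,[M+H]+,355.1031,355.103,1,phenylpropanoid
P5,7.98,Procyanidin B2,C30H26O12,[M+H]+,579.1497,579.1519;395.132,0,flavonoid
P6,8.71,Glaucolide B,C21H26O10,[M+H]+,441.1166,441.1155;207.0665;149.0586,0,terpenoid
P7,9.67,Quercetin-3'-glucuronide,C21H20O13,[M+H]+,481.0968,319.0479,0,flavonoid
P8,10.63,Hyperoside,C21H20O12,[M+H]+,465.1039,465.1038;303.0511,1,flavonoid
P9,10.82,Isoquercitrin,C21H20O12,[M+H]+,465.1054,465.1054;303.0535,1,flavonoid
P10,12.39,Acetylated isoquercitrin,C23H22O13,[M+H]+,507.1140,303.0454;507.113,0,flavonoid
P11,12.87,Quercetin 3-O-(6''-O-malonyl)-beta-D-glucoside,C24H22O15,[M+H]+,551.1035,551.1036;303.0510;163.1328,0,flavonoid
P12,18.77,Allamandin,C15H16O7,[M+H]+,309.2075,291.1953;273.1845;119.0869;79.0560,0,terpenoid
N1,1.28,Shikimic acid,C7H10O5,[M-H]-,173.0464,173.0450;93.0348,0,organic acid
N2,6.43,Unknown,,[M-H]-,707.1892,707.1954;353.0891;91.0589,0,unknown
N3,7.34,Chlorogenic acid,C16H18O9,[M-H]-,353.0889,85.0320;191.0576,1,phenylpropanoid
N4,7.58,Unknown,,[M-H]-,691.1916,691.1916;451.2208;162.8429;119.0521;93.0358,0,unknown
N5,7.75,Cryptochlorogenic acid,C16H18O9,[M-H]-,353.0889,135.0473;179.0372;191.0584;353.0905,0,phenylpropanoid
N6,7.98,Procyanidin B2,C30H26O12,[M-H]-,577.1391,289.0728;407.0795;577.1383,0,flavonoid
N7,10.09,Unknown,,[M-H]-,461.1694,415.1666;191.0588;149.0478,0,unknown
N8,10.62,Hyperoside,C21H20O12,[M-H]-,463.0882,301.0391;463.0923,1,flavonoid
N9,10.82,Isoquercitrin,C21H20O12,[M-H]-,463.0885,463.0902;301.0378;151.0055,1,flavonoid
N10,11.38,Quercetin 3-O-(6''-O-malonyl)-beta-D-galactoside,C24H22O15,[M-H]-,549.0926,505.1042;463.0896;301.0377;300.0301,0,flavonoid
N11,12.67,Quercetin 3-O-(6''-O-malonyl)-beta-D-glucoside,C24H22O15,[M-H]-,549.0916,505.1051;301.0377;300.0301,0,flavonoid
N12,17.68,Quercetin,C15H10O7,[M-H]-,301.0364,151.0055;179.0007;273.0428;301.0382,1,flavonoid
N13,18.08,Kaempferol,C15H10O6,[M-H]-,285.0417,93.0363;285.0436,1,flavonoid
N14,19.25,Hyperforin,C35H52O4,[M-H]-,535.3787,535.3778,0,quinone
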