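peak_id,ALT,AST,MDA,SOD,CAT,POD,starred
P1,-0.130,-0.181,0.077,0.223,0.453,-0.009,
P2,-0.045,-0.097,0.109,-0.154,0.413,0.003,
P3,0.226,0.304,0.115,-0.196,0.294,-0.360,
P4,-0.421,-0.291,-0.072,0.184,-0.301,0.462,
P5,-0.066,-0.382,0.275,0.114,0.019,0.092,
P6,-0.295,-0.405,-0.366,0.481,0.457,0.403,
P7,-0.385,-0.223,-0.217,0.397,0.382,-0.028,
P8,-0.131,-0.165,-0.075,0.244,0.396,0.222,
P9,-0.146,0.081,-0.072,0.088,0.271,-0.214,
P10,0.703,0.498,0.526,-0.549,-0.400,-0.404,ALT
P11,-0.152,-0.114,0.000,-0.097,0.023,0.114,
P12,0.543,0.302,0.114,-0.075,-0.422,-0.274,
N1,-0.207,0.125,-0.190,0.200,-0.339,0.067,
N2,0.115,0.103,-0.121,0.052,-0.339,-0.086,
N3,-0.138,-0.137,-0.220,0.307,0.161,0.173,
N4,-0.207,-0.086,-0.330,0.131,0.052,0.224,
N5,-0.139,-0.304,-0.213,0.093,0.521,0.194,
N6,-0.568,-0.447,-0.538,0.421,0.378,0.433,
N7,0.227,-0.035,-0.085,0.052,0.120,-0.142,
N8,-0.455,-0.286,-0.332,0.116,0.400,0.560,
N9,-0.436,-0.273,-0.250,0.114,0.656,0.170,CAT
N10,-0.340,-0.207,-0.295,0.075,0.290,0.146,
N11,-0.499,-0.631,-0.405,0.493,0.404,0.575,AST
N12,-0.074,-0.055,-0.426,0.304,-0.287,0.416,
N13,0.240,0.225,0.265,-0.386,0.211,-0.420,
N14,-0.296,-0.524,-0.363,0.254,0.701,0.251,CAT
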