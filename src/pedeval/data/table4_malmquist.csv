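dmu,2015=>2016,2016=>2017,2017=>2018,2018=>2019,2019=>2020,2020=>2021
Beijing,1.3474,0.9401,1.1579,0.8678,0.9907,1.3861
Tianjin,1.0608,1.0507,0.8043,1.0471,0.9977,0.8367
Hebei,1.0321,0.9063,1.0110,1.1700,0.8415,0.9620
Shanxi,1.1121,2.2595,1.3814,0.8369,0.9151,0.6582
Neimenggu,1.0831,1.0082,0.7754,1.0301,1.1141,1.0079
Liaoning,1.0371,1.0654,0.9468,1.0338,0.8026,1.0248
Jilin,1.1143,1.1543,0.8902,1.2602,1.1391,0.9545
Heilongjiang,1.0099,0.9891,0.9792,0.9991,1.1967,0.7822
Shanghai,1.0582,0.8512,1.0572,0.9407,0.8056,1.2851
Jiangsu,0.9037,1.3239,1.7101,1.0898,0.9027,0.6927
Zhejiang,0.9227,1.0934,1.0194,0.9934,0.6624,1.6944
Anhui,0.9481,1.2625,0.8385,1.6745,0.8909,0.9083
Fujian,1.0354,1.1314,0.8605,1.1568,0.8192,1.4026
Jiangxi,1.0051,1.0312,0.9775,0.9628,0.9124,1.0618
Shandong,0.9659,1.0209,1.0860,1.0275,0.9217,1.3509
Henan,1.0604,1.0732,1.1041,0.8972,0.8572,1.0912
Hubei,0.4151,1.0553,1.0067,0.9832,0.6863,1.2929
Hunan,1.0722,1.0741,1.0364,1.0052,0.8853,1.0472
Guangdong,0.9668,1.3910,0.8990,1.2463,0.7075,1.0987
Guangxi,1.0026,1.2056,0.8290,1.0753,0.8517,1.0469
Hainan,0.9085,1.0100,0.8613,0.9254,0.8388,1.1529
Chongqing,0.9355,1.0840,0.9596,1.1555,0.8082,1.0860
Sichuan,1.0046,1.1778,1.2952,1.1521,0.8900,1.3233
Guizhou,0.8683,1.5661,1.0584,0.9208,1.0030,0.8453
Yunnan,1.2020,0.9265,0.9845,1.2296,0.7724,0.9028
Xizang,0.8638,0.8573,1.6086,0.6851,1.0643,0.8955
Shaanxi,0.9887,1.0285,1.0348,0.9607,0.7798,1.1197
Gansu,0.9903,0.9881,1.0121,1.0105,0.9126,1.0341
Qinghai,1.0047,1.0697,0.9212,0.9309,0.9645,0.9793
Ningxia,0.8560,0.9730,0.8111,1.1555,0.9584,0.8313
Xinjiang,0.7389,1.7106,0.7675,1.0576,0.7900,1.0457
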