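sample_id,method,actual_class,flag,y_pre,y_dev
BFL-01,full,1,ok,0.836,0.116
BFL-01,CARS,1,ok,1.001,0.001
BFL-01,MCUVE,1,ok,0.654,0.245
BFL-01,SPA,1,ok,1.023,0.016
BFL-01,LPG,1,ok,0.805,0.138
BFL-05,full,1,ok,1.629,0.445
BFL-05,CARS,1,ok,0.774,0.160
BFL-05,MCUVE,1,ok,0.644,0.252
BFL-05,SPA,1,ok,1.230,0.163
BFL-05,LPG,1,ok,0.548,0.320
BFL-20,full,1,ok,1.536,0.379
BFL-20,CARS,1,ok,0.834,0.117
BFL-20,MCUVE,1,ok,0.541,0.324
BFL-20,SPA,1,ok,0.805,0.138
BFL-20,LPG,1,ok,0.749,0.178
BFL-34,full,1,ok,1.618,0.437
BFL-34,CARS,1,ok,0.719,0.199
BFL-34,MCUVE,1,ok,0.621,0.268
BFL-34,SPA,1,ok,1.205,0.145
BFL-34,LPG,1,ok,0.762,0.168
BFL-40,full,1,ok,0.835,0.117
BFL-40,CARS,1,ok,1.168,0.119
BFL-40,MCUVE,1,ok,0.711,0.204
BFL-40,SPA,1,ok,1.577,0.408
BFL-40,LPG,1,ok,0.822,0.126
BFL-48,full,1,SU,1.782,0.553
BFL-48,CARS,1,ok,1.119,0.084
BFL-48,MCUVE,1,ok,0.685,0.223
BFL-48,SPA,1,ok,1.400,0.283
BFL-48,LPG,1,ok,0.725,0.194
BFL-33,full,2,ok,2.004,0.003
BFL-33,CARS,2,ok,2.084,0.059
BFL-33,MCUVE,2,ok,1.756,0.173
BFL-33,SPA,2,ok,1.849,0.107
BFL-33,LPG,2,ok,1.758,0.171
BFL-42,full,2,SU,2.635,0.450
BFL-42,CARS,2,ok,1.554,0.315
BFL-42,MCUVE,2,ok,1.539,0.326
BFL-42,SPA,2,ok,1.870,0.092
BFL-42,LPG,2,ok,1.682,0.225
BFL-49,full,2,ok,1.928,0.051
BFL-49,CARS,2,ok,1.593,0.288
BFL-49,MCUVE,2,ok,2.192,0.136
BFL-49,SPA,2,ok,1.963,0.026
BFL-49,LPG,2,ok,1.920,0.057
BFL-54,full,2,ok,1.845,0.110
BFL-54,CARS,2,ok,1.967,0.023
BFL-54,MCUVE,2,ok,1.963,0.026
BFL-54,SPA,2,ok,1.720,0.198
BFL-54,LPG,2,ok,1.821,0.126
BFL-55,full,2,ok,1.751,0.176
BFL-55,CARS,2,ok,1.942,0.041
BFL-55,MCUVE,2,ok,1.882,0.083
BFL-55,SPA,2,ok,2.034,0.024
BFL-55,LPG,2,ok,1.716,0.201
BFL-12,full,3,ok,2.802,0.140
BFL-12,CARS,3,ok,3.019,0.013
BFL-12,MCUVE,3,ok,2.562,0.310
BFL-12,SPA,3,ok,2.880,0.085
BFL-12,LPG,3,ok,2.575,0.300
BFL-15,full,4,ok,3.844,0.110
BFL-15,CARS,4,ok,4.593,0.419
BFL-15,MCUVE,4,ok,3.744,0.181
BFL-15,SPA,4,ok,3.876,0.088
BFL-15,LPG,4,ok,3.582,0.296
BFL-37,full,4,ok,3.948,0.037
BFL-37,CARS,4,ok,3.712,0.204
BFL-37,MCUVE,4,ok,3.720,0.198
BFL-37,SPA,4,ok,3.900,0.071
BFL-37,LPG,4,ok,3.807,0.137
BFL-47,full,4,ok,3.893,0.076
BFL-47,CARS,4,ok,3.873,0.090
BFL-47,MCUVE,4,ok,3.861,0.098
BFL-47,SPA,4,ok,3.657,0.243
BFL-47,LPG,4,ok,3.817,0.129
BFL-04,full,5,SU,5.653,0.462
BFL-04,CARS,5,ok,4.901,0.070
BFL-04,MCUVE,5,ok,4.782,0.154
BFL-04,SPA,5,ok,4.565,0.308
BFL-04,LPG,5,ok,4.576,0.300
BFL-13,full,5,ok,4.813,0.132
BFL-13,CARS,5,ok,5.126,0.089
BFL-13,MCUVE,5,ok,5.117,0.083
BFL-13,SPA,5,ok,4.685,0.223
BFL-13,LPG,5,ok,4.790,0.149
BFL-16,full,5,ok,4.904,0.068
BFL-16,CARS,5,ok,5.047,0.033
BFL-16,MCUVE,5,ok,4.751,0.176
BFL-16,SPA,5,ok,4.818,0.129
BFL-16,LPG,5,ok,5.013,0.009
BFL-25,full,5,ok,4.965,0.025
BFL-25,CARS,5,ok,4.829,0.121
BFL-25,MCUVE,5,ok,4.995,0.004
BFL-25,SPA,5,ok,4.762,0.168
BFL-25,LPG,5,ok,4.829,0.121
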