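sample_id,method,actual_class,flag,y_pre,y_dev
FLP-01,full,1,ok,0.940,0.042
FLP-01,CARS,1,ok,0.551,0.317
FLP-01,MCUVE,1,ok,1.078,0.055
FLP-01,SPA,1,ok,0.816,0.130
FLP-01,LPG,1,ok,0.852,0.105
FLP-05,full,1,ok,1.622,0.440
FLP-05,CARS,1,ok,0.488,0.362
FLP-05,MCUVE,1,ok,0.598,0.285
FLP-05,SPA,1,ok,0.652,0.246
FLP-05,LPG,1,ok,0.434,0.400
FLP-32,full,1,ok,1.015,0.011
FLP-32,CARS,1,ok,1.114,0.081
FLP-32,MCUVE,1,ok,0.593,0.288
FLP-32,SPA,1,ok,0.627,0.264
FLP-32,LPG,1,ok,1.057,0.040
FLP-34,full,1,ok,1.608,0.430
FLP-34,CARS,1,UN,0.380,0.438
FLP-34,MCUVE,1,ok,1.290,0.205
FLP-34,SPA,1,ok,1.172,0.122
FLP-34,LPG,1,ok,0.974,0.018
FLP-40,full,1,ok,0.799,0.142
FLP-40,CARS,1,ok,1.133,0.094
FLP-40,MCUVE,1,ok,0.609,0.277
FLP-40,SPA,1,ok,1.013,0.009
FLP-40,LPG,1,ok,0.906,0.066
FLP-50,full,1,ok,0.810,0.134
FLP-50,CARS,1,ok,1.138,0.098
FLP-50,MCUVE,1,ok,0.866,0.095
FLP-50,SPA,1,ok,1.436,0.308
FLP-50,LPG,1,ok,0.870,0.092
FLP-59,full,1,ok,0.617,0.271
FLP-59,CARS,1,ok,0.971,0.021
FLP-59,MCUVE,1,ok,0.579,0.298
FLP-59,SPA,1,ok,1.321,0.227
FLP-59,LPG,1,ok,0.647,0.249
FLP-30,full,2,ok,1.895,0.074
FLP-30,CARS,2,ok,1.474,0.372
FLP-30,MCUVE,2,ok,2.465,0.329
FLP-30,SPA,2,ok,1.802,0.140
FLP-30,LPG,2,ok,1.737,0.186
FLP-46,full,2,ok,2.681,0.482
FLP-46,CARS,2,ok,1.502,0.352
FLP-46,MCUVE,2,ok,1.701,0.212
FLP-46,SPA,2,ok,2.470,0.332
FLP-46,LPG,2,ok,1.604,0.280
FLP-49,full,2,ok,2.587,0.415
FLP-49,CARS,2,ok,2.053,0.037
FLP-49,MCUVE,2,ok,1.509,0.347
FLP-49,SPA,2,ok,1.866,0.095
FLP-49,LPG,2,ok,1.521,0.339
FLP-54,full,2,ok,1.855,0.102
FLP-54,CARS,2,ok,1.566,0.307
FLP-54,MCUVE,2,ok,1.663,0.238
FLP-54,SPA,2,ok,1.657,0.243
FLP-54,LPG,2,ok,1.962,0.027
FLP-08,full,3,ok,2.989,0.008
FLP-08,CARS,3,ok,3.368,0.260
FLP-08,MCUVE,3,ok,3.039,0.028
FLP-08,SPA,3,ok,3.469,0.332
FLP-08,LPG,3,ok,2.899,0.072
FLP-26,full,4,ok,3.616,0.271
FLP-26,CARS,4,ok,3.900,0.071
FLP-26,MCUVE,4,ok,4.463,0.327
FLP-26,SPA,4,ok,3.779,0.156
FLP-26,LPG,4,ok,3.828,0.121
FLP-45,full,4,ok,4.412,0.291
FLP-45,CARS,4,ok,4.350,0.247
FLP-45,MCUVE,4,ok,3.723,0.196
FLP-45,SPA,4,SU,3.275,0.513
FLP-45,LPG,4,ok,4.487,0.344
FLP-04,full,5,ok,5.407,0.288
FLP-04,CARS,5,ok,5.474,0.335
FLP-04,MCUVE,5,ok,4.683,0.224
FLP-04,SPA,5,ok,5.321,0.227
FLP-04,LPG,5,ok,5.482,0.341
FLP-19,full,5,ok,5.557,0.394
FLP-19,CARS,5,ok,4.774,0.160
FLP-19,MCUVE,5,ok,5.025,0.018
FLP-19,SPA,5,ok,5.477,0.337
FLP-19,LPG,5,ok,4.666,0.236
FLP-23,full,5,SU,5.727,0.514
FLP-23,CARS,5,ok,4.785,0.152
FLP-23,MCUVE,5,ok,5.335,0.237
FLP-23,SPA,5,ok,4.589,0.291
FLP-23,LPG,5,ok,4.760,0.170
FLP-25,full,5,ok,4.777,0.158
FLP-25,CARS,5,ok,4.599,0.284
FLP-25,MCUVE,5,ok,4.789,0.149
FLP-25,SPA,5,ok,4.720,0.198
FLP-25,LPG,5,ok,4.809,0.135
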