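province,te_s1,pte_s1,se_s1,te_s3,pte_s3,se_s3
Beijing,0.86125,1,0.86125,1,1,1
Tianjin,0.96525,1,0.96525,1,1,1
Hebei,0.9425,0.9455,0.9965,0.9235,0.946,0.97625
Shanxi,0.9505,0.95625,0.99325,0.88175,0.9505,0.92825
Neimenggu,0.901,0.9335,0.96475,0.89775,0.9335,0.964
Liaoning,0.83575,0.91175,0.91675,0.906,0.9165,0.98875
Jilin,0.8905,0.9125,0.97475,0.84725,0.92425,0.91825
Heilongjiang,0.84675,0.91075,0.93175,0.89775,0.93475,0.96075
Shanghai,0.91225,0.995,0.91625,0.99275,0.9955,0.99725
Jiangsu,0.91025,0.94125,0.96675,0.93425,0.94075,0.99325
Zhejiang,0.935,0.956,0.97725,0.95275,0.955,0.99775
Anhui,0.94275,0.94725,0.99425,0.9165,0.9575,0.95225
Fujian,0.9445,0.95675,0.987,0.865,0.94075,0.92
Jiangxi,1,1,1,0.97425,1,0.97425
Shandong,0.9455,0.97175,0.973,0.961,0.97175,0.98925
Henan,1,1,1,1,1,1
Hubei,0.9145,0.98675,0.92725,0.975,0.988,0.98675
Hunan,0.98975,0.99625,0.9935,0.99475,0.99625,0.9985
Guangdong,0.882,0.99875,0.88325,0.9695,0.99875,0.9705
Guangxi,0.84575,0.86775,0.96975,0.865,0.86875,0.99625
Hainan,0.92875,0.94525,0.98225,0.8785,0.9155,0.959
Chongqing,0.9205,0.948,0.97125,0.9375,0.9495,0.9865
Sichuan,0.85225,0.9185,0.92825,0.9045,0.919,0.985
Guizhou,0.833,0.84175,0.9885,0.784,0.8355,0.93725
Yunnan,0.89525,0.90775,0.98675,0.858,0.91,0.94325
Tibet,1,1,1,0.91225,1,0.91225
Shaanxi,0.904,0.933,0.96625,0.8705,0.937,0.932
Gansu,0.95925,0.962,0.997,0.87875,0.964,0.9105
Qinghai,1,1,1,1,1,1
Ningxia,1,1,1,0.896,1,0.896
Xinjiang,0.83375,0.982,0.8465,0.96425,0.982,0.981
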