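province,y2017,y2018,y2019,y2020,mean
Beijing,0.816,0.907,1,0.722,0.861
Tianjin,0.861,1,1,1,0.965
Hebei,0.915,0.936,0.945,0.974,0.943
Liaoning,0.795,0.926,0.877,0.745,0.836
Shanghai,0.981,1,0.795,0.873,0.912
Jiangsu,0.862,0.862,0.933,0.984,0.910
Zhejiang,1,0.999,0.865,0.876,0.935
Fujian,0.87,0.945,0.963,1,0.946
Shandong,1,0.94,0.898,0.944,0.946
Guangdong,0.878,0.94,0.811,0.899,0.882
Hainan,0.875,0.913,0.927,1,0.929
Shanxi,0.851,0.986,1,0.965,0.9505
Jilin,0.875,0.894,1,0.793,0.8905
Heilongjiang,0.866,0.846,0.911,0.764,0.847
Anhui,0.79,0.981,1,1,0.943
Jiangxi,1,1,1,1,1
Henan,1,1,1,1,1
Hubei,0.825,0.914,0.939,0.98,0.915
Hunan,0.966,0.995,0.998,1,0.990
Neimenggu,0.894,1,0.875,0.835,0.901
Guangxi,0.623,0.807,0.953,1,0.846
Chongqing,0.956,0.878,0.887,0.961,0.921
Sichuan,0.823,0.806,0.845,0.935,0.852
Guizhou,0.666,0.976,0.828,0.862,0.833
Yunnan,0.871,0.885,0.891,0.934,0.895
Tibet,1,1,1,1,1
Shaanxi,0.97,0.996,0.908,0.742,0.904
Gansu,1,1,0.927,0.91,0.959
Qinghai,1,1,1,1,1
Ningxia,1,1,1,1,1
Xinjiang,0.717,0.984,0.971,0.663,0.834
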