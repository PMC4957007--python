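station,image_no,manual_count,manual_count_sd,manual_tl_um,manual_tl_sd_um,a_count,a_tl_um,rec_joined,rec_events,fil_obj,afil_aobj_pct
Ronciglione,1,7.6,0.5,1366,76,7,1239,2,2,39,31.4
Ronciglione,2,17.5,0.4,1953,96,15,1678,0,0,64,45.1
Ronciglione,3,8.3,0.4,1279,50,8,1288,2,2,35,31.8
Ronciglione,4,8.3,0.8,1249,100,7,1271,0,0,25,26.7
Ronciglione,5,4.3,0.2,796,95,3,705,0,0,26,23.8
Ronciglione,6,12.8,0.8,1671,90,16,1751,2,4,77,45.2
Ronciglione,7,7.9,0.2,1604,89,9,1549,0,0,43,38.9
Ronciglione,8,12.0,0.6,1819,110,12,2035,0,0,49,34.5
Ronciglione,9,10.4,0.6,1081,77,10,1029,0,0,44,33.4
Ronciglione,10,11.2,0.5,1603,52,11,1559,0,0,41,33.8
Caprarola,1,11.58,0.49,1871,149,12,1976,0,0,20,63.3
Caprarola,2,12.1,0.58,1958,32,12,2014,0,0,43,68.0
Caprarola,3,18.85,0.81,3826,177,20,4130,5,6,29,72.7
Caprarola,4,16.28,0.25,2090,128,16,1997,0,0,42,65.9
Caprarola,5,16.78,0.22,2429,116,17,2560,4,4,35,69.2
Caprarola,6,19.98,0.57,2148,76,19,2075,0,0,28,28.2
Caprarola,7,20.83,0.62,2600,167,21,2740,0,0,42,67.0
Caprarola,8,26.7,0.27,2492,155,25,2477,2,2,46,38.9
Caprarola,9,32.78,0.67,3447,159,34,3756,2,2,46,41.6
Caprarola,10,23.98,0.92,2596,81,22,2643,0,0,33,30.5
Albano,1,20,0.79,4725,58,19,4543,3,4,25,79.6
Albano,2,32.1,0.65,4582,114,30,4137,3,4,39,75.2
Albano,3,33.35,0.65,5324,136,29,5168,2,4,36,76.5
Albano,4,27.85,0.47,4455,76,22,4448,5,6,30,72.8
Albano,5,20.73,0.73,2809,123,18,2783,0,0,22,57.0
Albano,6,26.63,0.87,5944,141,24,6007,6,6,30,78.5
Albano,7,20.35,0.6,2304,127,17,2181,2,2,29,64.6
Albano,8,25.4,0.37,3438,41,19,3218,0,0,27,69.0
Albano,9,27.68,0.9,5485,165,25,5535,4,5,27,78.9
Albano,10,24.43,0.38,4256,134,22,4093,0,0,25,80.0
Nemi,1,6.888,0.28,1083,39,6,980,0,0,17,27.2
Nemi,2,5,0.49,546,64,5,489,0,0,24,26.2
Nemi,3,4.113,0.24,589,55,4,515,0,0,10,18.4
Nemi,4,4.688,0.19,808,56,5,746,0,0,20,26.5
Nemi,5,1.963,0.24,531,49,2,537,0,0,10,23.3
Nemi,6,6.063,0.34,940,81,5,850,0,0,23,29.5
Nemi,7,6.175,0.24,814,39,4,720,0,0,26,30.2
Nemi,8,1.863,0.28,278,45,2,277,0,0,23,27.2
Nemi,9,2.9,0.34,789,51,3,850,0,0,44,37.7
Nemi,10,3.763,0.21,1154,56,5,1034,0,0,18,28.2
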