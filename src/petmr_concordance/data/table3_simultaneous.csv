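patient,suv_max,suv_mean,adc_min_r1,adc_min_r3,adc_mean_r1,adc_mean_r3,distance_mm_r1,distance_mm_r3,diameter_mm
1,22.6,13.4,451,334,1329,1296,20.2,21.8,74.5
2,7.2,4.3,6,6,1609,1584,56.5,56.5,96.4
3,14.4,8.4,12,12,1036,1016,28.7,28.7,93.6
4,8.5,4.6,553,222,1504,1612,48.0,33.0,85.6
5,6.1,3.7,235,564,1238,1430,4.8,4.0,29.2
6,9.5,5.9,422,381,1937,1339,3.1,8.6,24.0
7,8.0,4.8,779,575,1688,1694,9.5,12.6,34.2
8,19.7,11.5,49,49,1028,1052,24.8,24.8,54.4
9,8.1,4.9,553,638,1150,1164,7.7,3.9,20.4
10,2.6,1.4,228,337,1105,1121,22.9,22.4,46.9
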