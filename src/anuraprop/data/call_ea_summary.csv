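species,substrate,distance_m,mean_db,sd_db,min_db,max_db
Pelophylax perezi,Water,1,2.17,4.74,-5.82,10.60
Pelophylax perezi,Water,2,1.20,3.66,-5.95,10.72
Pelophylax perezi,Water,4,-0.80,1.89,-9.52,9.30
Pelophylax perezi,Water,8,3.42,1.89,-8.82,18.13
Pelophylax perezi,Water,mean,1.63,6.83,,
Pelophylax perezi,Soil,1,1.37,8.71,-4.90,7.39
Pelophylax perezi,Soil,2,4.75,2.08,-9.87,14.78
Pelophylax perezi,Soil,4,4.25,6.34,-4.45,11.25
Pelophylax perezi,Soil,8,8.96,2.43,-1.66,17.91
Pelophylax perezi,Soil,mean,5.27,7.91,,
Lithobates catesbeianus,Water,1,-0.62,10.79,-4.11,3.15
Lithobates catesbeianus,Water,2,-4.82,9.43,-11.39,-1.27
Lithobates catesbeianus,Water,4,-1.64,3.10,-9.78,8.02
Lithobates catesbeianus,Water,8,0.28,0.72,-7.15,11.03
Lithobates catesbeianus,Water,mean,-1.50,7.76,,
Lithobates catesbeianus,Soil,1,0.82,10.10,-6.03,4.11
Lithobates catesbeianus,Soil,2,3.96,8.15,-1.73,10.46
Lithobates catesbeianus,Soil,4,1.53,4.24,-5.28,9.76
Lithobates catesbeianus,Soil,8,5.02,4.97,-4.12,12.41
Lithobates catesbeianus,Soil,mean,3.00,14.23,,
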