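substrate,category,range_khz,mean_db,sd_db,min_db,max_db
Water,F1,0.2-0.5,1.76,5.61,-5.28,10.18
Water,F2,0.6-1.0,0.57,5.20,-5.97,9.99
Water,F3,1.1-2.0,-2.74,3.53,-16.12,10.76
Water,F4,2.1-3.0,1.49,1.68,-19.52,19.55
Water,F5,3.5-5.0,6.71,0.05,-12.16,22.33
Soil,F1,0.2-0.5,0.22,0.12,-18.75,15.00
Soil,F2,0.6-1.0,2.70,1.03,-18.65,19.60
Soil,F3,1.1-2.0,6.57,2.80,-18.09,26.22
Soil,F4,2.1-3.0,9.39,2.77,-11.41,26.96
Soil,F5,3.5-5.0,6.26,1.13,-13.95,20.97
Total,F1,0.2-0.5,1.02,2.43,-18.75,15.00
Total,F2,0.6-1.0,1.70,0.33,-18.65,19.60
Total,F3,1.1-2.0,3.11,3.82,-18.09,26.22
Total,F4,2.1-3.0,6.31,3.69,-19.52,26.96
Total,F5,3.5-5.0,6.49,0.58,-13.95,22.33
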