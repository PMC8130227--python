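table,organ,sex,patient_id,scanner,kvp,dw_cm,ctdivol_obtcm_mGy,nd_obtcm,ctdivol_atcm_mGy,nd_atcm,delta_pct
3,breast,female,2,Flash,100,20.0,8.0,0.84,11.4,1.05,-20
3,breast,female,5,Flash,100,20.7,7.8,0.79,12.3,0.76,4
3,breast,female,6,Flash,100,22.2,6.1,1.17,10.1,1.22,-5
3,breast,female,8,Flash,100,22.9,8.0,0.96,6.7,1.11,-13
3,breast,female,11,Flash,120,25.1,9.9,0.87,11.4,0.95,-9
3,breast,female,16,Force,120,18.8,6.6,1.15,6.8,0.96,21
3,breast,female,18,Force,120,20.0,7.7,0.80,6.3,0.81,-1
3,breast,female,19,Force,120,20.3,6.9,0.94,5.4,0.83,14
3,breast,female,22,Force,120,21.7,8.2,0.83,8.4,0.96,-14
3,breast,female,24,Force,120,22.6,10.7,0.88,10.8,1.01,-12
3,breast,female,25,Force,120,23.6,9.3,0.95,9.5,1.36,-31
3,breast,female,26,Force,120,23.7,10.4,0.93,8.0,0.83,12
3,breast,female,27,Force,120,23.8,11.9,0.70,11.9,1.00,-30
3,breast,female,31,Force,120,27.0,12.9,0.88,13.0,1.14,-23
3,breast,female,32,Force,120,27.2,12.9,0.70,10.4,0.89,-22
3,breast,female,33,Force,120,27.5,14.6,0.63,11.8,0.76,-17
3,breast,female,34,Force,120,33.2,16.9,0.73,17.3,0.96,-25
4,lung,female,2,Flash,100,20.0,8.0,1.14,11.4,1.19,-4
4,lung,female,5,Flash,100,20.7,7.8,1.03,12.3,0.92,12
4,lung,female,6,Flash,100,22.2,6.1,1.58,10.1,1.26,26
4,lung,female,8,Flash,100,22.9,8.0,1.17,6.7,1.12,5
4,lung,female,11,Flash,120,25.1,9.9,1.20,11.4,1.09,11
4,lung,female,16,Force,120,18.8,6.6,1.35,6.8,1.33,1
4,lung,female,18,Force,120,20.0,7.7,1.25,6.3,1.18,6
4,lung,female,19,Force,120,20.3,6.9,1.37,5.4,1.29,6
4,lung,female,22,Force,120,21.7,8.2,1.17,8.4,1.31,-11
4,lung,female,24,Force,120,22.6,10.7,1.15,10.8,1.28,-10
4,lung,female,25,Force,120,23.6,9.3,1.25,9.5,1.47,-15
4,lung,female,26,Force,120,23.7,10.4,1.15,8.0,1.21,-5
4,lung,female,27,Force,120,23.8,11.9,1.03,11.9,1.26,-18
4,lung,female,31,Force,120,27.0,12.9,0.97,13.0,1.13,-15
4,lung,female,32,Force,120,27.2,12.9,1.02,10.8,1.04,-2
4,lung,female,33,Force,120,27.5,14.6,0.78,11.8,0.85,-9
4,lung,female,34,Force,120,33.2,16.9,0.97,17.3,1.05,-8
5,lung,male,1,Flash,100,19.9,9.3,1.29,11.5,1.14,13
5,lung,male,3,Flash,100,20.7,10.3,1.24,11.3,1.04,20
5,lung,male,4,Flash,100,20.7,8.2,1.20,10.6,0.94,28
5,lung,male,7,Flash,120,22.3,15.2,1.26,19.5,0.99,26
5,lung,male,9,Flash,100,23.6,11.4,1.09,13.0,0.85,28
5,lung,male,10,Flash,120,24.7,11.5,1.27,11.9,1.15,11
5,lung,male,12,Flash,100,26.6,13.0,0.99,17.0,0.87,14
5,lung,male,13,Flash,100,30.4,14.9,1.01,19.7,0.89,14
5,lung,male,14,Flash,120,32.8,18.9,0.96,14.9,0.84,14
5,lung,male,15,Flash,120,36.2,23.2,0.80,23.5,0.86,-6
5,lung,male,17,Force,120,17.8,9.8,1.05,7.2,1.01,4
5,lung,male,20,Force,120,20.3,11.8,1.06,8.0,1.05,1
5,lung,male,21,Force,120,21.0,10.7,1.12,7.9,1.04,7
5,lung,male,23,Force,120,22.1,11.2,0.95,9.3,1.04,-9
5,lung,male,28,Force,120,24.1,12.3,1.04,14.5,1.29,-19
5,lung,male,29,Force,120,25.2,12.6,1.26,9.9,0.93,36
5,lung,male,30,Force,120,25.5,18.0,0.70,11.6,0.89,-21
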