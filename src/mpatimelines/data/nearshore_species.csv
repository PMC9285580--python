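name,max_age,L_mat,L_c,M,F,L_inf,k,a_0,a_m,a_c,p,w,sigma_R
Kelp rockfish,25,18.00,25.00,0.20,0.17,37.80,0.23,-0.70,3,3,6.29e-05,3.17,0.53
Blue rockfish,44,27.09,21.03,0.14,0.17,38.15,0.17,-1.15,6,4,9.77e-05,3.09,0.78
Black rockfish,50,40.23,29.00,0.14,0.05,45.11,0.33,0.75,7,4,5.81e-05,3.19,0.5
Gopher rockfish,30,17.00,25.40,0.20,0.17,34.10,0.23,-0.50,3,6,1.30e-04,3.08,0.5
Lingcod,25,49.30,60.11,0.25,0.23,96.74,0.17,-1.56,3,4,7.13e-06,3.41,1
Copper rockfish,50,32.00,29.70,0.09,0.08,56.50,0.14,-1.00,5,5,8.98e-06,3.13,0.8
California scorpionfish,21,17.00,25.40,0.25,0.19,40.29,0.13,-2.69,2,5,1.95e-05,3.17,0.5
Brown rockfish,34,27.50,27.50,0.14,0.13,51.40,0.16,-0.55,4,4,1.02e-05,3.07,0.8
Yellowtail rockfish,64,37.00,28.50,0.11,0.06,49.88,0.18,-1.21,6,4,6.69e-05,3.00,0.8
Vermillion rockfish,65,36.00,22.00,0.10,0.14,53.92,0.16,-0.18,7,3,1.46e-04,3.04,0.7
Bocaccio,55,35.50,38.00,0.15,0.01,70.00,0.22,-0.69,3,3,1.32e-05,3.00,1
Cabezon,17,34.00,38.10,0.28,0.12,49.90,0.28,-1.23,3,4,5.50e-06,3.19,1
China rockfish,83,27.00,30.48,0.06,0.09,33.62,0.23,-0.26,7,10,7.79e-05,3.18,0.8
Kelp greenling,25,30.00,30.48,0.30,0.17,41.15,0.24,-1.91,3,4,4.18e-05,3.00,0.45
California sheephead,53,24.00,30.48,0.25,0.25,46.70,0.18,1.00,4,6,2.89e-05,2.86,0.61
Red sea urchin,100,18,20,0.07,0.36,33.15,0.23,-0.7,3,6,1.27e-03,2.71,0.5
Kelp bass,33,22.3,30.48,0.18,0.12,69.8,0.06,-3.5,3,6,2.73e-06,3.27,0.5
Olive rockfish,30,27,30.48,0.14,0.07,33.62,0.23,-0.26,4,3,1.08e-05,2.968,0.5
Black & Yellow rockfish,30,17.5,24,0.2,0.17,24.95,0.23,-0.38,5,14,1.12e-04,3.114,0.5
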