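region,vehicle_mean,vehicle_se,mg3_mean,mg3_se,mg10_mean,mg10_se,mg30_mean,mg30_se,p_value,omega_sq
"Parietal ctx",7,3.6,0,0.0,0,0.0,0,0.0,0.001,0.980
"CA2",1,0.3,0,0.0,0,0.0,0,0.0,0.005,0.631
"Retrosplenial rostral ctx",22,5.5,0,0.0,1,0.6,0,0.4,0.006,0.625
"Triangular septal n.",3,1.3,0,0.0,0,0.0,0,0.0,0.006,0.624
"Prelimbic ctx",14,3.9,0,0.0,1,1.6,2,1.7,0.009,0.561
"Dentate gyrus ventral",8,2.9,5,3.4,1,0.7,16,5.8,0.009,0.555
"CA3 hippocampus ventral",7,3.1,3,2.9,0,0.2,9,3.8,0.013,0.508
"Somatosensory ctx hindlimb",9,4.8,0,0.3,0,0.0,0,0.0,0.017,0.469
"Anterior thalamic nuclei",7,3.5,0,0.0,0,0.0,0,0.2,0.018,0.456
"Secondary motor ctx",29,11.7,6,6.0,1,1.0,1,0.7,0.019,0.451
"Reuniens n.",11,6.9,1,1.0,0,0.0,0,0.0,0.019,0.448
"Anterior olfactory n.",23,5.1,10,4.8,3,1.8,16,5.3,0.021,0.434
"Insular ctx",75,14.9,19,5.5,16,11.2,33,7.2,0.022,0.428
"Accumbens core",6,3.3,0,0.3,0,0.0,4,2.3,0.023,0.422
"Entorhinal ctx",90,33.2,20,6.6,57,8.7,108,29.8,0.025,0.411
"Retrosplenial caudal ctx",108,29.1,8,4.5,11,6.9,13,6.9,0.025,0.410
"Bed n. stria terminalis",6,5.0,1,0.5,0,0.0,0,0.0,0.026,0.407
"Subthalamus",1,0.8,0,0.0,0,0.0,1,0.4,0.029,0.390
"Lateral septal n.",49,11.9,14,10.7,7,3.0,9,2.3,0.031,0.381
"Anterior cingulate area",29,11.1,2,1.4,4,2.1,0,0.3,0.038,0.349
"Primary motor ctx",32,13.8,6,5.5,2,2.2,2,1.1,0.039,0.347
"Lateral orbital ctx",9,2.9,2,1.8,1,0.6,5,3.2,0.044,0.327
"White matter",27,11.6,8,3.6,5,2.0,15,4.0,0.045,0.325
"Medial septum",3,1.7,0,0.0,0,0.0,0,0.0,0.047,0.318
"Globus pallidus",5,4.4,0,0.0,0,0.0,0,0.0,0.048,0.316
"Somatosensory ctx trunk",2,1.4,0,0.0,0,0.0,0,0.0,0.048,0.316
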