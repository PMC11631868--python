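region,vehicle_mean,vehicle_se,mg3_mean,mg3_se,mg10_mean,mg10_se,mg30_mean,mg30_se,p_value,omega_sq
"Posterior thalamus",2,1.5,74,13.4,85,5.3,43,13.2,0.005,0.515
"CA2",1,0.5,4,0.6,6,0.7,3,0.7,0.006,0.664
"Ventral medial striatum",1,0.3,97,6.0,70,15.0,52,17.0,0.006,0.664
"Red n.",0,0.0,7,1.8,9,0.9,4,1.3,0.006,0.632
"Parafascicular thalamus",1,0.5,40,9.9,50,8.2,25,8.6,0.007,0.572
"Accumbens core",7,3.0,78,7.9,62,13.3,32,9.3,0.007,0.590
"Retrosplenial rostral ctx",6,6.0,79,7.3,60,6.9,41,13.1,0.007,0.609
"Reticular n. midbrain",18,6.0,161,38.4,150,11.2,74,27.1,0.008,0.456
"Dorsal medial striatum",4,2.2,160,10.1,125,21.6,93,33.3,0.010,0.529
"Dorsal lateral striatum",1,0.6,220,25.1,196,28.6,135,41.4,0.012,0.583
"Dentate gyrus ventral",13,6.2,53,7.1,54,8.9,24,11.1,0.013,0.521
"Claustrum",3,1.1,21,2.9,20,4.3,11,4.0,0.013,0.572
"Prelimbic ctx",1,0.3,95,13.1,71,21.9,51,19.0,0.013,0.530
"Ventral posteromedial thalamus",0,0.0,41,9.7,39,7.8,25,7.1,0.013,0.418
"Anterior pretectal n.",1,1.3,19,2.3,22,1.9,12,5.1,0.014,0.565
"Lateral posterior thalamus",3,3.0,52,11.2,53,8.1,30,13.6,0.014,0.451
"Dentate gyrus dorsal",5,3.3,82,25.1,74,13.6,51,14.3,0.014,0.387
"Superior colliculus",27,11.7,146,32.8,143,12.0,103,19.4,0.015,0.407
"Primary motor ctx",45,27.1,333,44.0,259,55.6,198,58.2,0.015,0.470
"Somatosensory ctx jaw",16,7.5,173,35.4,139,33.4,98,26.7,0.015,0.427
"Somatosensory ctx hindlimb",6,6.0,81,12.3,65,9.7,64,13.2,0.016,0.524
"Ventral posteriolateral thalamus",1,0.5,42,6.2,38,7.1,28,6.7,0.016,0.408
"Pontine reticular n. oral",7,2.5,54,16.3,66,7.8,31,12.2,0.017,0.437
"Somatosensory ctx upper lip",17,5.2,155,38.2,134,18.9,116,23.8,0.017,0.394
"Ventrolateral thalamus",1,0.5,35,8.0,40,4.3,26,9.2,0.018,0.533
"Zona incerta",0,0.0,32,11.5,18,9.2,12,4.3,0.018,0.359
"CA1 dorsal",4,2.2,137,27.0,136,12.9,96,28.3,0.019,0.414
"Visual 2 ctx",15,2.9,181,24.9,188,7.5,146,28.6,0.019,0.436
"White matter, anterior",110,16.4,526,97.8,501,66.5,413,57.6,0.019,0.349
"Retrosplenial caudal ctx",13,4.5,220,24.9,187,22.5,170,41.4,0.021,0.432
"Somatosensory ctx barrel field",7,3.2,223,55.4,210,28.1,174,47.2,0.021,0.428
"Parietal ctx",3,2.5,66,13.0,69,12.7,56,15.6,0.022,0.531
"Temporal ctx",24,9.7,55,2.8,46,3.0,43,4.7,0.023,0.418
"Ventral orbital ctx",16,6.2,63,5.2,61,8.3,29,12.8,0.023,0.392
"Bed n. stria terminalis",0,0.0,31,3.4,28,11.7,22,10.7,0.024,0.469
"Somatosensory ctx forelimb",12,11.2,135,24.9,113,19.1,90,26.6,0.024,0.433
"Ventral lateral striatum",19,5.9,212,37.6,197,35.5,163,37.2,0.024,0.419
"Visual 1 ctx",4,2.1,153,24.2,163,19.6,134,30.8,0.024,0.369
"Somatosensory ctx trunk",0,0.3,12,3.2,13,3.8,10,2.3,0.025,0.483
"Reticular n.",0,0.3,31,9.4,32,5.2,26,6.8,0.026,0.374
"4th cerebellar lobule",54,4.6,95,13.7,97,8.1,53,21.2,0.026,0.355
"White matter, posterior",8,3.9,69,23.6,74,8.0,51,18.4,0.026,0.390
"CA3 hippocampus ventral",7,4.8,33,6.9,33,7.1,15,6.9,0.026,0.426
"Globus pallidus",0,0.0,18,2.3,12,6.2,12,3.1,0.027,0.470
"Lateral septal n.",6,5.8,115,27.9,93,25.9,82,32.8,0.028,0.391
"Anterior thalamic nuclei",4,2.8,39,7.8,36,4.2,27,10.0,0.030,0.446
"Extended amygdala",0,0.0,10,3.1,5,2.0,4,1.4,0.030,0.395
"Secondary somatosensory ctx",12,6.6,97,26.6,111,10.7,94,13.2,0.030,0.322
"Central amygdaloid n.",6,3.8,40,9.1,41,4.3,18,10.5,0.031,0.399
"Ventral anterior thalamus",1,0.5,16,3.3,15,1.4,9,3.9,0.032,0.461
"Infralimbic ctx",3,1.7,43,11.2,32,4.3,25,10.0,0.032,0.346
"Medial dorsal thalamus",1,1.0,16,4.3,20,4.4,13,5.8,0.035,0.452
"CA1 hippocampus ventral",26,12.8,94,5.1,74,12.9,44,21.3,0.035,0.357
"Lateral geniculate",0,0.3,20,11.1,14,3.2,15,4.1,0.036,0.288
"Subiculum dorsal",2,1.3,33,8.1,33,5.2,27,8.7,0.038,0.303
"Raphe linear",0,0.0,9,3.5,8,1.5,4,2.0,0.038,0.372
"Lateral orbital ctx",20,8.4,122,20.0,101,23.2,50,25.2,0.039,0.360
"Insular ctx",123,10.1,295,81.5,317,44.8,247,34.8,0.039,0.362
"Perirhinal ctx",43,18.9,98,17.1,103,8.3,57,20.2,0.040,0.329
"Somatosensory ctx shoulder",2,2.3,18,1.2,13,3.5,14,3.2,0.040,0.434
"CA3 dorsal",10,5.9,70,22.9,68,10.8,57,17.1,0.042,0.310
"Anterior cingulate area",20,15.5,167,36.0,151,32.9,136,31.7,0.043,0.344
"Locus coeruleus",0,0.3,0,0.0,2,0.6,1,0.4,0.043,0.417
"6th cerebellar lobule",74,13.4,91,28.5,146,8.2,88,32.2,0.044,0.354
"Auditory ctx",52,20.5,196,57.9,232,11.9,172,31.8,0.045,0.322
"Reuniens n.",0,0.0,14,5.2,15,6.9,11,4.1,0.045,0.394
"Ventromedial thalamus",0,0.0,28,7.9,25,7.1,16,5.8,0.046,0.330
"Pontine reticular n. caudal",29,11.5,81,30.0,109,11.8,50,19.9,0.047,0.239
"Triangular septal n.",0,0.0,5,1.9,3,1.1,4,1.5,0.047,0.412
"Caudal piriform ctx",61,8.1,135,25.5,134,9.7,95,21.6,0.050,0.302
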