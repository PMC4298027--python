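species,individual,brain_size,pch_l,fm_l,pf_l,pch_r,fm_r,pf_r
Homo_sapiens,5694,1216.00,46.33,51.91,42.56,46.67,38.18,59.12
Homo_sapiens,6895,1110.00,51.04,26.02,57.46,50.98,31.81,51.76
Homo_sapiens,1696,1622.00,72.22,61.92,69.25,70.09,61.85,71.40
Homo_sapiens,14686,1437.00,47.55,58.08,59.01,46.19,49.08,77.04
Pan_troglodytes,280,444.98,12.62,20.85,17.70,12.37,21.91,16.74
Pan_troglodytes,497,378.00,15.17,14.44,11.52,15.17,13.69,12.57
Gorilla_gorilla,375,434.36,20.68,21.79,13.61,20.01,23.56,13.36
Gorilla_gorilla,8214,376.00,10.40,13.27,8.07,11.19,14.14,7.83
Hylobates_lar,1203,98.36,3.61,3.78,3.02,3.70,3.61,3.08
Hylobates_lar,397,107.00,3.87,5.04,2.70,3.90,5.23,2.43
Papio_anubis,97,184.36,4.05,6.42,4.72,4.24,6.44,4.69
Cercopithecus_mitis,261,72.39,1.34,2.29,1.50,1.42,2.25,1.79
Cercopithecus_ascanius,219,59.36,1.15,1.85,1.29,1.13,1.82,1.33
Erythrocebus_patas,1341,93.73,1.55,3.22,1.88,1.60,3.48,1.82
Erythrocebus_patas,1545,89.00,1.87,3.24,2.04,1.84,3.32,1.91
Miopithecus_talapoin,1171,39.67,0.69,1.26,1.04,0.66,1.11,1.17
Miopithecus_talapoin,1201,38.32,0.57,0.98,0.79,0.57,0.97,0.73
Nasalis_larvatus,1365,62.02,1.77,2.50,0.81,1.88,1.86,1.04
Procolobus_badius,213,75.97,2.04,2.61,1.81,2.11,2.69,1.84
Alouatta_seniculus,1184,45.17,1.00,1.53,0.88,1.08,1.58,1.60
Ateles_geoffroyi,1000,102.70,2.65,3.74,2.84,2.63,3.48,3.68
Lagothrix_lagotricha,1571,88.16,2.16,3.25,2.17,2.18,2.91,2.26
Pithecia_monachus,1180,32.82,0.69,0.96,0.45,0.71,1.02,0.95
Cebus_albifrons,1200,77.03,1.72,2.47,1.74,1.65,2.75,2.01
Cebus_albifrons,6062,68.53,1.80,1.63,1.94,1.78,1.68,2.56
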