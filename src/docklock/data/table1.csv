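complex,kd_um,kd_err,kd_nmr_um,kd_nmr_err,dg,dg_err,dh,dh_err,neg_tds,neg_tds_err,n,n_err,koff,koff_err,koff_cest,koff_cest_err,kon,kon_err,kd_method
EBH/4MACF,10400,280,,,-11.312,0.066,,,,,,,,,,,,,NMR_CSP
EBH/6MACF,1730,240,,,-15.76,0.34,,,,,,,,,,,,,NMR_CSP
EBH/9MACF,34.00,0.56,,,-25.49,0.04,-24.95,0.06,-0.52,0.1,1.00,0.04,,,,,,,ITC
EBH/11MACF,3.5,1.0,4.91,0.09,-31.20,0.81,-39.6,4.5,8.4,3.6,1.13,0.17,130.2,2.1,143.6,6.0,37,11,ITC
EBH/11MACF-LLL,0.287,0.088,,,-37.50,0.87,-35.8,5.3,-4.9,1.4,1.01,0.11,,,,,,,ITC
EBH/11MACF-VLL,0.081,0.009,0.32,0.012,-40.50,0.25,-40.2,1.2,-1.300,0.091,0.906,0.056,15.63,0.12,57.5,8.7,192,21,ITC
EBH/11MACF-VLLRK,0.016,0.003,,,-44.60,0.47,-27.80,0.30,-16.80,0.32,1.18,0.14,,,,,,,ITC
EBH/11MACF-VLLRK-150mM-NaCl,0.198,0.012,,,-38.5,1.5,-34.4,1.8,-4.18,0.17,1.03,0.05,,,,,,,ITC
EBH/13CK5P2,0.021,0.022,,,-46.4,5.0,-36.4,8.8,-9.6,5.0,0.876,0.093,,,,,,,ITC
EBH-dC/6MACF,7070,1880,,,-12.27,0.66,,,,,,,,,,,,,NMR_CSP
EBH-dC/11MACF,41.5,8.8,26.6,0.51,-24.62,1.7,-29.1,1.8,1.11,0.92,1.08,0.35,1900,54,,,45.8,9.8,ITC
EBH-dC/11MACF-VLL,18.7,3.1,25.62,0.82,-27.00,0.43,-24.9,4.5,-2.1,4.8,0.99,0.18,1541,79,,,82,14,ITC
EBH-dC/11MACF-VLLRK,6.29,0.47,,,-29.70,0.17,-24.6,4.6,-5.1,4.6,0.960,0.056,,,,,,,ITC
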