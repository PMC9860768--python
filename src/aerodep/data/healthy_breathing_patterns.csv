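subject,d_um,phase_speed,Q_in_lpm,Q_ex_lpm,TV_L,FRC_L
H1,1.0,slow,19.26,20.94,1.116,3.26
H2,1.0,slow,19.08,19.32,1.073,3.38
H3,1.0,slow,19.86,20.10,1.101,3.44
H4,1.0,slow,17.70,18.24,0.979,3.51
H5,1.0,slow,18.72,18.66,1.041,2.67
H6,1.0,slow,17.64,17.82,0.984,3.43
H7,1.0,slow,18.18,17.76,1.009,3.31
H1,1.0,fast,43.56,45.30,1.127,3.26
H2,1.0,fast,41.40,40.02,1.019,3.38
H3,1.0,fast,41.94,41.64,1.038,3.44
H4,1.0,fast,39.18,40.50,1.012,3.51
H5,1.0,fast,40.56,42.18,1.043,2.67
H6,1.0,fast,42.90,40.02,0.924,3.43
H7,1.0,fast,41.16,40.74,0.923,3.31
H1,2.9,slow,21.66,23.16,1.254,3.26
H2,2.9,slow,19.38,18.96,1.064,3.38
H3,2.9,slow,17.70,17.94,0.987,3.44
H4,2.9,slow,17.16,17.70,0.972,3.51
H5,2.9,slow,18.66,18.00,1.023,2.67
H6,2.9,slow,18.18,19.26,1.043,3.43
H7,2.9,slow,18.30,19.14,1.249,3.31
H1,2.9,fast,45.48,49.02,1.164,3.26
H2,2.9,fast,44.58,44.22,1.135,3.38
H3,2.9,fast,39.96,39.60,0.994,3.44
H4,2.9,fast,37.62,41.40,0.993,3.51
H5,2.9,fast,40.32,40.14,1.035,2.67
H6,2.9,fast,40.08,39.24,0.900,3.43
H7,2.9,fast,40.26,41.64,0.901,3.31
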