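# Published Henderson-Hasselbalch protonation fractions of the predicted
# hASIC1a pH-sensor residues at the five (conformational state, pH)
# conditions: closed at pH 7.4, start/end of activation at pH 6.0
# (closed/open-state pKa) and start/end of steady-state desensitization
# at pH 6.8 (closed/desensitized-state pKa).  Used as a printed-table
# input for driver/stabilizer classification.
domain,site,f_closed,f_start_activation,f_end_activation,f_start_ssd,f_end_ssd
palm,His70,0.05,0.55,0.53,0.16,0.17
palm,His72,0.00,0.10,0.20,0.02,0.01
palm,His73,0.01,0.20,0.22,0.04,0.01
palm,Lys76,0.49,0.96,0.67,0.79,0.74
palm,Asp78,0.00,0.10,0.01,0.02,0.00
palm,Glu79,0.00,0.01,0.69,0.00,0.92
palm,His173,0.03,0.45,0.36,0.11,0.08
palm,Glu277,0.00,0.04,0.08,0.01,0.09
palm,Lys291,0.93,1.00,0.11,0.98,0.98
palm,Lys374,0.16,0.83,0.00,0.44,0.00
palm,Glu375,0.00,0.00,0.78,0.00,0.02
palm,Glu413,0.00,0.00,0.19,0.00,0.01
palm,Glu418,0.00,0.00,0.30,0.00,0.77
acidic_pocket,Lys211,0.99,1.00,0.03,1.00,0.00
acidic_pocket,Glu219,0.00,0.00,0.01,0.00,0.03
acidic_pocket,Glu238,0.00,0.00,0.63,0.00,0.91
acidic_pocket,Glu242,0.00,0.00,0.08,0.00,0.13
acidic_pocket,Lys246,0.82,0.99,0.42,0.95,0.21
acidic_pocket,Lys343,0.85,0.99,0.99,0.96,0.00
acidic_pocket,Asp347,0.00,0.03,0.93,0.00,0.25
acidic_pocket,Asp351,0.00,0.07,0.01,0.01,0.10
acidic_pocket,Glu355,0.00,0.03,0.00,0.00,0.04
acidic_pocket,Asp409,0.00,0.00,0.00,0.00,0.88
finger,His110,0.03,0.41,0.16,0.10,0.08
thumb,Asp298,0.00,0.01,0.54,0.00,0.01
thumb,Glu315,0.00,0.01,0.65,0.00,0.48
thumb,His329,0.00,0.09,0.06,0.02,0.02
thumb,Asp357,0.00,0.01,0.02,0.00,0.06
thumb,Glu364,0.00,0.01,0.28,0.00,0.00
beta_ball,Glu97,0.00,0.00,0.31,0.00,0.94
beta_ball,Lys193,0.47,0.96,0.99,0.78,0.75
beta_ball,Glu254,0.00,0.09,0.12,0.02,0.01
beta_ball,Asp259,0.00,0.00,0.00,0.00,0.10
knuckle,Lys384,0.93,1.00,0.97,0.98,0.91
knuckle,Lys388,0.83,0.99,0.80,0.95,0.97
transmembrane,Glu63,0.84,0.99,1.00,0.95,0.90
transmembrane,Asp434,0.92,1.00,0.83,0.98,1.00
transmembrane,Asp455,0.88,0.99,1.00,0.97,0.88
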