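# Twelve side-chain property scales used for pH50/pHD50 regressions.
# Transcribed from the standard literature sources; user-replaceable.
# bulkiness, polarity: Zimmerman, Eliezer & Simha, J Theor Biol 21 (1968)
# flexibility: Bhaskaran & Ponnuswamy, Int J Pept Protein Res 32 (1988)
# hydropathy: Kyte & Doolittle, J Mol Biol 157 (1982)
# alpha/beta/turn propensity: Chou & Fasman, Adv Enzymol 47 (1978)
# coil propensity: Deleage & Roux, Protein Eng 1 (1987)
# size: Dawson, in "The Biochemical Genetics of Man" (1972)
# surface: Chothia, J Mol Biol 105 (1976), tripeptide accessible surface
# hydrogen_donor/hydrogen_acceptor: IMGT aide-memoire side-chain H-bond counts
amino_acid,bulkiness,flexibility,hydrogen_acceptor,hydrogen_donor,hydropathy,polarity,alpha_propensity,beta_propensity,turn_propensity,coil_propensity,size,surface
A,11.50,0.357,0,0,1.8,0.00,1.42,0.83,0.66,0.824,2.5,115
R,14.28,0.529,0,5,-4.5,52.00,0.98,0.93,0.95,0.893,7.5,225
N,12.82,0.463,2,2,-3.5,3.38,0.67,0.89,1.56,1.167,5.0,160
D,11.68,0.511,4,0,-3.5,49.70,1.01,0.54,1.46,1.197,2.5,150
C,13.46,0.346,0,1,2.5,1.48,0.70,1.19,1.19,0.953,3.0,135
Q,14.45,0.493,2,2,-3.5,3.53,1.11,1.10,0.98,0.947,6.0,180
E,13.57,0.497,4,0,-3.5,49.90,1.51,0.37,0.74,0.761,5.0,190
G,3.40,0.544,0,0,-0.4,0.00,0.57,0.75,1.56,1.251,0.5,75
H,13.69,0.323,1,2,-3.2,51.60,1.00,0.87,0.95,1.068,6.0,195
I,21.40,0.462,0,0,4.5,0.13,1.08,1.60,0.47,0.886,5.5,175
L,21.40,0.365,0,0,3.8,0.13,1.21,1.30,0.59,0.884,5.5,170
K,15.71,0.466,0,3,-3.9,49.50,1.16,0.74,1.01,0.897,7.0,200
M,16.25,0.295,1,0,1.9,1.43,1.45,1.05,0.60,0.810,6.0,185
F,19.80,0.314,0,0,2.8,0.35,1.13,1.38,0.60,0.797,6.5,210
P,17.43,0.509,0,0,-1.6,1.58,0.57,0.55,1.52,1.540,5.5,145
S,9.47,0.507,2,1,-0.8,1.67,0.77,0.75,1.43,1.130,3.0,115
T,15.77,0.444,2,1,-0.7,1.66,0.83,1.19,0.96,1.148,5.0,140
W,21.67,0.305,0,1,-0.9,2.10,1.08,1.37,0.96,0.941,7.0,255
Y,18.03,0.420,1,1,-1.3,1.61,0.69,1.47,1.14,1.109,7.0,230
V,21.57,0.386,0,0,4.2,0.13,1.06,1.70,0.50,0.772,5.0,155
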