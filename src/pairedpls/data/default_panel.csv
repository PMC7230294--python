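metabolite_id,class,lloq,uloq,acyl_carbons
C0,free_carnitine,1.47911,591.642,
C2,acylcarnitine,0.00459834,1.83933,
C3,acylcarnitine,0.00982284,3.92913,
C3:1,acylcarnitine,0.00166799,0.667197,
C3-OH,acylcarnitine,0.00334211,1.33684,
C3-DC,acylcarnitine,0.0531023,21.2409,
C4,acylcarnitine,0.093455,37.382,
C4:1,acylcarnitine,0.00996734,3.98693,
C4-OH,acylcarnitine,0.0057453,2.29812,
C5,acylcarnitine,0.0032278,1.29112,
C5:1,acylcarnitine,0.00386133,1.54453,
C5-OH,acylcarnitine,0.00528523,2.11409,
C5-DC,acylcarnitine,0.0210807,8.43227,
C5-M-DC,acylcarnitine,0.00107665,0.430658,
C6,acylcarnitine,0.0197934,7.91738,
C6:1,acylcarnitine,0.00373752,1.49501,
C7-DC,acylcarnitine,0.028878,11.5512,
C8,acylcarnitine,0.00158112,0.632446,
C9,acylcarnitine,0.00224513,0.898053,
C10,acylcarnitine,0.00225295,0.901179,
C10:1,acylcarnitine,0.00338161,1.35264,
C10:2,acylcarnitine,0.00209931,0.839724,
C12,acylcarnitine,0.0184989,7.39957,
C12:1,acylcarnitine,0.00550543,2.20217,
C12-DC,acylcarnitine,0.0769126,30.765,
C14,acylcarnitine,0.00112999,0.451996,
C14:1,acylcarnitine,0.00255179,1.02072,
C14:1-OH,acylcarnitine,0.00477253,1.90901,
C14:2,acylcarnitine,0.00169272,0.677088,
C14:2-OH,acylcarnitine,0.00104494,0.417977,
C16,acylcarnitine,0.00705533,2.82213,
C16:1,acylcarnitine,0.0677154,27.0861,
C16:1-OH,acylcarnitine,0.0265085,10.6034,
C16:2,acylcarnitine,0.00244693,0.978771,
C16:2-OH,acylcarnitine,0.0483806,19.3522,
C16-OH,acylcarnitine,0.0110009,4.40035,
C18,acylcarnitine,0.00794278,3.17711,
C18:1,acylcarnitine,0.00321345,1.28538,
C18:1-OH,acylcarnitine,0.0175037,7.0015,
C18:2,acylcarnitine,0.087153,34.8612,
H1,hexose,268.015,107206.0,
Ala,amino_acid,2.61729,1046.92,
Arg,amino_acid,3.45355,1381.42,
Asn,amino_acid,1.56035,624.138,
Asp,amino_acid,9.03003,3612.01,
Cit,amino_acid,1.2371,494.84,
Gln,amino_acid,7.85798,3143.19,
Glu,amino_acid,0.954527,381.811,
Gly,amino_acid,5.82311,2329.24,
His,amino_acid,1.52498,609.993,
Ile,amino_acid,2.28799,915.196,
Leu,amino_acid,17.2214,6888.55,
Lys,amino_acid,0.529483,211.793,
Met,amino_acid,18.1006,7240.24,
Orn,amino_acid,4.09608,1638.43,
Phe,amino_acid,5.00759,2003.04,
Pro,amino_acid,1.15212,460.849,
Ser,amino_acid,0.706085,282.434,
Thr,amino_acid,12.8484,5139.35,
Trp,amino_acid,4.15317,1661.27,
Tyr,amino_acid,6.97731,2790.92,
Val,amino_acid,5.2563,2102.52,
ADMA,biogenic_amine,0.0325614,13.0246,
SDMA,biogenic_amine,0.0206443,8.25771,
total DMA,biogenic_amine,0.00335184,1.34074,
alpha-AAA,biogenic_amine,0.505537,202.215,
c4-OH-Pro,biogenic_amine,0.168834,67.5336,
t4-OH-Pro,biogenic_amine,0.229879,91.9517,
Carnosine,biogenic_amine,0.00951306,3.80522,
Creatinine,biogenic_amine,0.0741489,29.6595,
DOPA,biogenic_amine,0.21035,84.14,
Dopamine,biogenic_amine,0.307415,122.966,
Histamine,biogenic_amine,0.201309,80.5234,
Kynurenine,biogenic_amine,0.0596014,23.8406,
Met-SO,biogenic_amine,0.190081,76.0322,
Nitro-Tyr,biogenic_amine,0.106478,42.5912,
PEA,biogenic_amine,0.802562,321.025,
Putrescine,biogenic_amine,0.0104204,4.16814,
Sarcosine,biogenic_amine,0.00594621,2.37848,
Serotonin,biogenic_amine,0.152486,60.9943,
Spermidine,biogenic_amine,0.0646059,25.8424,
Spermine,biogenic_amine,0.0465664,18.6266,
Taurine,biogenic_amine,0.983473,393.389,
lysoPC a C14:0,lysoPC,0.132281,52.9123,14
lysoPC a C16:0,lysoPC,0.306276,122.51,16
lysoPC a C16:1,lysoPC,1.32967,531.867,16
lysoPC a C17:0,lysoPC,1.39566,558.265,17
lysoPC a C18:0,lysoPC,0.0375745,15.0298,18
lysoPC a C18:1,lysoPC,0.400815,160.326,18
lysoPC a C18:2,lysoPC,0.0275711,11.0284,18
lysoPC a C20:3,lysoPC,1.8306,732.241,20
lysoPC a C20:4,lysoPC,0.024994,9.9976,20
lysoPC a C24:0,lysoPC,0.757884,303.153,24
lysoPC a C26:0,lysoPC,3.74148,1496.59,26
lysoPC a C26:1,lysoPC,0.101112,40.4447,26
lysoPC a C28:0,lysoPC,0.291063,116.425,28
lysoPC a C28:1,lysoPC,0.479241,191.696,28
PC aa C24:0,PC_aa,7.14499,2857.99,
PC aa C26:0,PC_aa,0.208901,83.5605,
PC aa C28:1,PC_aa,2.50833,1003.33,
PC aa C30:0,PC_aa,1.41264,565.054,
PC aa C30:2,PC_aa,0.0907268,36.2907,
PC aa C32:0,PC_aa,9.4416,3776.64,
PC aa C32:1,PC_aa,0.0785553,31.4221,
PC aa C32:2,PC_aa,1.68095,672.381,
PC aa C32:3,PC_aa,0.888484,355.394,
PC aa C34:1,PC_aa,0.194303,77.7211,
PC aa C34:2,PC_aa,0.0898324,35.933,
PC aa C34:3,PC_aa,6.21972,2487.89,
PC aa C34:4,PC_aa,8.06973,3227.89,
PC aa C36:0,PC_aa,0.474036,189.614,
PC aa C36:1,PC_aa,0.257694,103.078,
PC aa C36:2,PC_aa,0.0497085,19.8834,
PC aa C36:3,PC_aa,0.155507,62.2028,
PC aa C36:4,PC_aa,3.86354,1545.41,
PC aa C36:5,PC_aa,0.0325141,13.0056,
PC aa C36:6,PC_aa,0.0708201,28.328,
PC aa C38:0,PC_aa,0.0283722,11.3489,
PC aa C38:1,PC_aa,0.302203,120.881,
PC aa C38:3,PC_aa,1.20702,482.807,
PC aa C38:4,PC_aa,2.79128,1116.51,
PC aa C38:5,PC_aa,0.518122,207.249,
PC aa C38:6,PC_aa,0.168789,67.5156,
PC aa C40:1,PC_aa,0.484107,193.643,
PC aa C40:2,PC_aa,0.363377,145.351,
PC aa C40:3,PC_aa,0.617493,246.997,
PC aa C40:4,PC_aa,3.00066,1200.26,
PC aa C40:5,PC_aa,0.140201,56.0804,
PC aa C40:6,PC_aa,7.16719,2866.88,
PC aa C42:0,PC_aa,0.237457,94.9828,
PC aa C42:1,PC_aa,0.479868,191.947,
PC aa C42:2,PC_aa,2.09854,839.416,
PC aa C42:4,PC_aa,0.771805,308.722,
PC aa C42:5,PC_aa,0.762662,305.065,
PC aa C42:6,PC_aa,0.0473146,18.9259,
PC ae C30:0,PC_ae,0.369191,147.676,
PC ae C30:1,PC_ae,0.0889501,35.58,
PC ae C30:2,PC_ae,0.391402,156.561,
PC ae C32:1,PC_ae,0.133005,53.202,
PC ae C32:2,PC_ae,0.679634,271.854,
PC ae C34:0,PC_ae,0.353063,141.225,
PC ae C34:1,PC_ae,0.315308,126.123,
PC ae C34:2,PC_ae,0.769272,307.709,
PC ae C34:3,PC_ae,0.219846,87.9383,
PC ae C36:0,PC_ae,0.0265474,10.619,
PC ae C36:1,PC_ae,0.0277523,11.1009,
PC ae C36:2,PC_ae,0.050955,20.382,
PC ae C36:3,PC_ae,0.315458,126.183,
PC ae C36:4,PC_ae,0.764305,305.722,
PC ae C36:5,PC_ae,0.117215,46.886,
PC ae C38:0,PC_ae,0.0858903,34.3561,
PC ae C38:1,PC_ae,0.546458,218.583,
PC ae C38:2,PC_ae,0.593875,237.55,
PC ae C38:3,PC_ae,0.17978,71.9121,
PC ae C38:4,PC_ae,0.106025,42.4098,
PC ae C38:5,PC_ae,0.587185,234.874,
PC ae C38:6,PC_ae,0.0218364,8.73455,
PC ae C40:1,PC_ae,0.0167734,6.70935,
PC ae C40:2,PC_ae,0.542126,216.85,
PC ae C40:3,PC_ae,0.0724199,28.968,
PC ae C40:4,PC_ae,0.0481436,19.2574,
PC ae C40:5,PC_ae,0.0177791,7.11163,
PC ae C40:6,PC_ae,0.242873,97.1491,
PC ae C42:1,PC_ae,0.972395,388.958,
PC ae C42:2,PC_ae,0.173543,69.4172,
PC ae C42:3,PC_ae,0.28211,112.844,
PC ae C42:4,PC_ae,0.0247599,9.90395,
PC ae C42:5,PC_ae,0.0162963,6.51853,
PC ae C44:3,PC_ae,0.972871,389.148,
PC ae C44:4,PC_ae,0.0519515,20.7806,
PC ae C44:5,PC_ae,0.0481355,19.2542,
PC ae C44:6,PC_ae,0.714581,285.832,
PC ae C46:3,PC_ae,0.211705,84.6821,
SM C16:0,sphingomyelin,1.51315,605.259,16
SM C16:1,sphingomyelin,0.278958,111.583,16
SM C18:0,sphingomyelin,0.320171,128.068,18
SM C18:1,sphingomyelin,0.285339,114.136,18
SM C20:2,sphingomyelin,0.153311,61.3243,20
SM C22:3,sphingomyelin,1.0942,437.679,22
SM C24:0,sphingomyelin,0.305851,122.34,24
SM C24:1,sphingomyelin,1.3201,528.041,24
SM C26:0,sphingomyelin,1.24675,498.701,26
SM C26:1,sphingomyelin,1.2938,517.519,26
SM (OH) C14:1,sphingomyelin,1.19605,478.418,14
SM (OH) C16:1,sphingomyelin,0.882196,352.879,16
SM (OH) C22:1,sphingomyelin,0.273024,109.21,22
SM (OH) C22:2,sphingomyelin,0.285602,114.241,22
SM (OH) C24:1,sphingomyelin,3.12844,1251.37,24
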