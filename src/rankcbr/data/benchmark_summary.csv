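model,index,MIN,AVG,STD,MAX
K-NN,precision,0.5000,0.6506,0.1490,0.8571
SVM,precision,0.8571,0.8857,0.0639,1.0000
SCUCC,precision,0.7000,0.9067,0.1362,1.0000
CLCBR,precision,0.6000,0.7633,0.1529,1.0000
ETCBR,precision,0.7500,0.8917,0.1087,1.0000
LWCBR,precision,0.3333,0.6578,0.1985,0.8000
RWCBR,precision,0.7778,0.9111,0.1217,1.0000
K-NN,recall,0.7143,0.8285,0.0639,0.8571
SVM,recall,0.8571,0.8857,0.0639,1.0000
SCUCC,recall,0.2857,0.6857,0.2748,1.0000
CLCBR,recall,0.5714,0.7714,0.1917,1.0000
ETCBR,recall,0.7143,0.8571,0.1429,1.0000
LWCBR,recall,0.2857,0.7428,0.3097,1.0000
RWCBR,recall,0.7143,0.9143,0.1278,1.0000
K-NN,f1,0.5882,0.7236,0.1067,0.8571
SVM,f1,0.8571,0.8857,0.0639,1.0000
SCUCC,f1,0.4444,0.7375,0.1795,0.9231
CLCBR,f1,0.6154,0.7576,0.1514,1.0000
ETCBR,f1,0.7692,0.8672,0.0965,1.0000
LWCBR,f1,0.3077,0.6861,0.2320,0.8750
RWCBR,f1,0.8333,0.9013,0.0637,1.0000
K-NN,g,0.5976,0.7221,0.1088,0.8571
SVM,g,0.8571,0.8857,0.0639,1.0000
SCUCC,g,0.5345,0.7649,0.1451,0.9258
CLCBR,g,0.6171,0.7624,0.1488,1.0000
ETCBR,g,0.7715,0.8708,0.0951,1.0000
LWCBR,g,0.3086,0.6931,0.2345,0.8819
RWCBR,g,0.8452,0.9070,0.0593,1.0000
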