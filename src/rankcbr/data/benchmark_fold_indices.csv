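fold,model,precision,recall,f1,g
1,K-NN,0.5000,0.7143,0.5882,0.5976
1,SVM,0.8571,0.8571,0.8571,0.8571
1,SCUCC,1.0000,0.2857,0.4444,0.5345
1,CLCBR,0.6667,0.5714,0.6154,0.6171
1,ETCBR,1.0000,0.7143,0.8333,0.8452
1,LWCBR,0.8000,0.5714,0.6667,0.6761
1,RWCBR,1.0000,0.7143,0.8333,0.8452
2,K-NN,0.8571,0.8571,0.8571,0.8571
2,SVM,0.8571,0.8571,0.8571,0.8571
2,SCUCC,1.0000,0.8571,0.9231,0.9258
2,CLCBR,0.8000,0.5714,0.6667,0.6761
2,ETCBR,0.7500,0.8571,0.8000,0.8018
2,LWCBR,0.3333,0.2857,0.3077,0.3086
2,RWCBR,1.0000,0.8571,0.9231,0.9258
3,K-NN,0.6000,0.8571,0.7059,0.7171
3,SVM,0.8571,0.8571,0.8571,0.8571
3,SCUCC,0.8333,0.7143,0.7692,0.7715
3,CLCBR,0.7500,0.8571,0.8000,0.8018
3,ETCBR,0.8333,0.7143,0.7692,0.7715
3,LWCBR,0.7778,1.0000,0.8750,0.8819
3,RWCBR,0.7778,1.0000,0.8750,0.8819
4,K-NN,0.7500,0.8571,0.8000,0.8018
4,SVM,1.0000,1.0000,1.0000,1.0000
4,SCUCC,1.0000,0.5714,0.7273,0.7559
4,CLCBR,1.0000,1.0000,1.0000,1.0000
4,ETCBR,0.8750,1.0000,0.9333,0.9354
4,LWCBR,0.7778,1.0000,0.8750,0.8819
4,RWCBR,1.0000,1.0000,1.0000,1.0000
5,K-NN,0.5455,0.8571,0.6667,0.6838
5,SVM,0.8571,0.8571,0.8571,0.8571
5,SCUCC,0.7000,1.0000,0.8235,0.8366
5,CLCBR,0.6000,0.8571,0.7059,0.7171
5,ETCBR,1.0000,1.0000,1.0000,1.0000
5,LWCBR,0.6000,0.8571,0.7059,0.7171
5,RWCBR,0.7778,1.0000,0.8750,0.8819
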