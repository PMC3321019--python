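gene_ids	regulation
A2M,LAMP1,MYBL2,HLA-DQA1,MMP12,LIPA,HG1723-HT1729,GSTM4,CDA,HG4069-HT4339,SPP1	up
RPE65,SLC14A1,CXCL6,LAMB1,DNAH14,CNTF,D14822,M64936,IFI27,PFDN4,COL4A5,PDE3A,HG3934-HT4204,HTN1,BAMBI,MAP2,HG2260-HT2349	down
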