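geneA	geneB	combined_score
PARD6G	CDC42	982
PARD6B	CDC42	951
PARD6G	PARD6B	763
CDC42	LLGL2	801
LLGL2	SCRIB	912
SCRIB	DLG1	934
MPP5	CRB3	965
MPP5	PARD6B	842
CRB3	PARD6G	715
DVL3	CTNNB1	923
DVL3	GSK3B	884
CTNNB1	GSK3B	971
CTNNB1	CDH1	994
STK3	MOB1B	978
STK3	YAP1	861
YAP1	NF2	793
NF2	STK3	845
YAP1	CTNNB1	742
RHOA	CDC42	887
RHOA	LLGL2	412
GSK3B	MYC	655
MYC	YAP1	701
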