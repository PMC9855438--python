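pair_id	ligand	receptor
DLL1_NOTCH1	DLL1	NOTCH1
DLL1_NOTCH2	DLL1	NOTCH2
DLL1_NOTCH3	DLL1	NOTCH3
DLL1_NOTCH4	DLL1	NOTCH4
DLK1_NOTCH1	DLK1	NOTCH1
DLK1_NOTCH2	DLK1	NOTCH2
DLK1_NOTCH3	DLK1	NOTCH3
DLK1_NOTCH4	DLK1	NOTCH4
TGFB1_TGFBR	TGFB1	TGFBR1,TGFBR2
TGFB2_TGFBR	TGFB2	TGFBR1,TGFBR2
TGFB3_TGFBR	TGFB3	TGFBR1,TGFBR2
SPP1_CD44	SPP1	CD44
CXCL12_CXCR4	CXCL12	CXCR4
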