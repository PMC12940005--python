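keyword,genes
gpx,GPX1
glutathione,GPX1
sod,SOD2
superoxide,SOD2
catalase,CAT
peroxidase,GPX1
hsp70,HSPA1A
heat-shock,HSPA1A
tlr2,TLR2
toll-like,TLR2
il6,IL6
tnf,TNF
il1b,IL1B
il8,CXCL8
cortisol,NR3C1
dhea,CYP17A1
npy,NPY
lactoferrin,LTF
defensin,DEFB1;DEFA1
iga,PIGR
mucin,MUC5B;MUC7
histatin,HTN1;HTN3
lysozyme,LYZ
amylase,AMY1A
candida,CLEC7A
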