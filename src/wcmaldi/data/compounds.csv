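name,formula,class,acyl_carbons
heme B,C34H32FeN4O4,porphyrin,
PC(34:1),C42H82NO8P,PC lipid,34
PC(36:1),C44H86NO8P,PC lipid,36
imatinib,C29H31N7O,BCR-ABL inhibitor,
dasatinib,C22H26ClN7O2S,BCR-ABL inhibitor,
nilotinib,C28H22F3N7O,BCR-ABL inhibitor,
vandetanib,C22H24BrFN4O2,BCR-ABL inhibitor,
sunitinib,C22H27FN4O2,tyrosine kinase inhibitor,
sorafenib,C21H16ClF3N4O3,tyrosine kinase inhibitor,
chloroquine,C18H26ClN3,antimalarial,
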