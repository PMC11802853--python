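ligand,receptor,tag
CCL1,CCR8,chemokine
CCL17,CCR4,chemokine
CCL19,CCR7,chemokine
CCL20,CCR6,chemokine
CCL22,CCR4,chemokine
CXCL9,CXCR3,chemokine
CXCL10,CXCR3,chemokine
CXCL12,CXCR4,chemokine
CXCL13,CXCR5,chemokine
CXCL16,CXCR6,chemokine
IL2,IL2RA,cytokine
IL6,IL6R,cytokine
IL10,IL10RA,cytokine
IL15,IL15RA,cytokine
IL21,IL21R,cytokine
TGFB1,TGFBR1,cytokine
TNF,TNFRSF1A,cytokine
IFNG,IFNGR1,cytokine
CD274,PDCD1,checkpoint
PDCD1LG2,PDCD1,checkpoint
CD80,CTLA4,checkpoint
CD86,CD28,checkpoint
LGALS9,HAVCR2,checkpoint
PVR,TIGIT,checkpoint
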