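gene	immport	enrichr	category
ADCY3	0	1	Human T-cell leukemia virus 1 infection
ADCY9	0	1	Human T-cell leukemia virus 1 infection
ATM	0	1	Human T-cell leukemia virus 1 infection
CCL11	1	0	Cytokines/Antimicrobials/Chemokines
CCL28	1	0	Cytokines/Antimicrobials/Chemokines
CGA	1	0	Cytokines
CRHR1	1	0	Cytokine receptors
CSK	1	0	Antimicrobials
DEFB136	1	0	Antimicrobials
GABBR1	0	1	Inflammatory Response
HELZ2	0	1	Interferon alpha Response
IFITM2	0	1	Interferon alpha/beta signaling R-HSA-909733/Interferon alpha Response
IKZF1	0	1	Development of pulmonary dendritic cells and macrophage subsets WP3892
IP6K2	0	1	Interferon alpha/beta signaling R-HSA-909733
IRF1	1	1	Antimicrobials/Interferon alpha/beta signaling R-HSA-909733/Interferon alpha Response
IRF6	0	1	Interferon alpha/beta signaling R-HSA-909733/Inflammatory Response
ITGB3	0	1	Inflammatory Response
ITGB8	0	1	Inflammatory Response
LAT	1	1	Natural killer cell cytotoxicity/TCR signaling pathway/Modulators of TCR signaling and T cell activation WP5072
MAPT	1	0	Antimicrobials
NFATC1	1	1	Natural killer cell cytotoxicity/TCR signaling pathway/BCR signaling pathway/Human T-cell leukemia virus 1 infection
NR3C1	1	0	Cytokine receptors
PDK1	1	0	TCR signaling pathway
PIK3R1	1	1	Natural killer cell cytotoxicity/TCR signaling pathway/BCR signaling pathway/Modulators of TCR signaling and T cell activation WP5072/Human T-cell leukemia virus 1 infection
PPARG	1	0	Cytokine receptors/Antimicrobials
RASA2	0	1	Natural killer cell cytotoxicity/TCR signaling pathway/BCR signaling pathway/Modulators of TCR signaling and T cell activation WP5072/Human T-cell leukemia virus 1 infection
SH2B3	0	1	TCR signaling pathway/Modulators of TCR signaling and T cell activation WP5072
SKAP1	0	1	TCR signaling pathway
SPI1	0	1	Development of pulmonary dendritic cells and macrophage subsets WP3892/Human T-cell leukemia virus 1 infection
TCF7L2	1	0	Antimicrobials
TERT	0	1	Human T-cell leukemia virus 1 infection
TRIM27	1	0	Antimicrobials
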