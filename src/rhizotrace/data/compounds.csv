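# Biomarker compound reference table.
# n_carbon_added is the number of carbon atoms introduced by the standard
# derivatization for each class (FAME methylation for PLFA; aldononitrile
# acetates for amino sugars; methoxycarbonyl methyl esters for amino acids).
# The added-carbon counts are illustrative defaults and can be overridden by
# supplying a user table with the same columns.
compound,biomarker_class,formula,n_carbon,n_carbon_added
GlcN,AS,C6H13NO5,6,8
GalN,AS,C6H13NO5,6,8
ManN,AS,C6H13NO5,6,8
MurN,AS,C9H17NO7,9,6
i15:0,PLFA,C15H30O2,15,1
a15:0,PLFA,C15H30O2,15,1
C15:0,PLFA,C15H30O2,15,1
C16:0,PLFA,C16H32O2,16,1
16:1w7,PLFA,C16H30O2,16,1
10Me16:0,PLFA,C17H34O2,17,1
cy17:0,PLFA,C17H32O2,17,1
C18:0,PLFA,C18H36O2,18,1
18:1w9,PLFA,C18H34O2,18,1
18:2w6,PLFA,C18H32O2,18,1
cy19:0,PLFA,C19H36O2,19,1
alanine,AA,C3H7NO2,3,3
Asx,AA,C4H7NO4,4,3
Glx,AA,C5H9NO4,5,3
glycine,AA,C2H5NO2,2,3
isoleucine,AA,C6H13NO2,6,3
lysine,AA,C6H14N2O2,6,3
phenylalanine,AA,C9H11NO2,9,3
Pro/Thr,AA,C5H9NO2,5,3
serine,AA,C3H7NO3,3,3
tyrosine,AA,C9H11NO3,9,3
valine,AA,C5H11NO2,5,3
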