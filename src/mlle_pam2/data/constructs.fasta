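>MLLE_544-626 first=544 PABPC1 MLLE domain crystallisation construct (human, residues 544-626)
PLTASMLASAPPQEQKQMLGERLFPLIQAMHPTLAGKITGMLLEIDNSELLHMLESPESL
RSKVDEAVAVLQAHQAKEAAQKA
>eRF3_67-81 first=67 eRF3 PAM2-N peptide (GSPT1 residues 67-81)
SQLNVNAKPFVPNVH
>eRF3_76-90 first=76 eRF3 PAM2-C peptide (GSPT1 residues 76-90)
FVPNVHAAEFVPSFL
>GST_scar first=539 N-terminal cloning scar left by PreScission cleavage of the GST fusion
GPLGS
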