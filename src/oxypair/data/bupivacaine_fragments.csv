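# Default product-ion core library for bupivacaine phase-I metabolites.
# formula: even-electron cation composition (includes the transferred proton)
# classes: metabolite classes the unmodified core applies to ("*" = all)
# oxygen_site_classes: classes whose inserted oxygen(s) can reside on this core
formula,classes,oxygen_site_classes
C4H8N,*,
C5H8N,*,DAO;HO
C5H10N,*,DAH;HO;DH
C6H10N,*,HO
C6H12N,*,DH
C9H18N,H;DH;O;HO,H;DH
C9H16N,O;HO,O;HO
C14H20N2O,DA;DAH;DAO;DADH,DAH;DAO;DADH
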