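species	risk_group
Klebsiella pneumoniae	2
Enterobacter hormaechei	2
Salmonella enterica	2
Campylobacter jejuni	2
Escherichia coli	2
Clostridioides difficile	2
Staphylococcus aureus	2
Streptococcus pyogenes	2
Enterococcus faecium	2
Pseudomonas aeruginosa	2
Acinetobacter baumannii	2
Haemophilus influenzae	2
Helicobacter pylori	2
Listeria monocytogenes	2
Shigella flexneri	2
Shigella sonnei	2
Yersinia enterocolitica	2
Vibrio cholerae	1
Vibrio fluvialis	1
Vibrio vulnificus	1
Vibrio parahaemolyticus	2
Brucella ovis	1
Brucella melitensis	1
Chlamydia trachomatis	1
Mycobacterium tuberculosis	1
Bordetella pertussis	2
Neisseria meningitidis	2
Proteus mirabilis	2
Serratia marcescens	2
Citrobacter freundii	2
Morganella morganii	2
Aeromonas hydrophila	2
Plesiomonas shigelloides	2
Bacillus cereus	2
Clostridium perfringens	2
Clostridium botulinum	1
Fusobacterium nucleatum	2
Providencia stuartii	2
Edwardsiella tarda	2
Arcobacter butzleri	2
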