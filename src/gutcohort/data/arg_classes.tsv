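# Prefix-keyed drug-class map for ResFinder-style gene names.
# Longest matching prefix wins; genes with no match roll up as "unassigned".
prefix	drug_class
aph	aminoglycoside
aac	aminoglycoside
aad	aminoglycoside
ant	aminoglycoside
rmt	aminoglycoside
bla	beta-lactam
mec	beta-lactam
tet	tetracycline
otr	tetracycline
erm	macrolide
mef	macrolide
msr	macrolide
mph	macrolide
lnu	lincosamide
lsa	lincosamide
vga	streptogramin
vat	streptogramin
sul	sulphonamide
dfr	trimethoprim
qnr	quinolone
oqx	quinolone
fos	fosfomycin
van	glycopeptide
mcr	colistin
cat	phenicol
flo	phenicol
cml	phenicol
cfr	oxazolidinone
optr	oxazolidinone
arr	rifampicin
nim	nitroimidazole
fus	fusidic-acid
ere	macrolide
str	aminoglycoside
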