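# Elemental compositions (Hill formulas) of the species of the core
# network and of the screened products.  Phosphorylated intermediates
# include their phosphate groups; acyl-CoA species count the acyl moiety
# only (the CoA handle is conserved and untracked).  The biomass species
# has no fixed formula; its carbon bookkeeping uses the precursor drain
# of the biomass equation.
glc	C6H12O6
glc_ext	C6H12O6
g6p	C6H13O9P
f6p	C6H13O9P
fbp	C6H14O12P2
dhap	C3H7O6P
gap	C3H7O6P
bpg	C3H8O10P2
pg3	C3H7O7P
pg2	C3H7O7P
pep	C3H5O6P
pyr	C3H4O3
accoa	C2H3O
ac	C2H4O2
etoh	C2H6O
lac	C3H6O3
for	CH2O2
cit	C6H8O7
icit	C6H8O7
akg	C5H6O5
succoa	C4H5O3
succ	C4H6O4
fum	C4H4O4
fum_ext	C4H4O4
mal	C4H6O5
oaa	C4H4O5
glx	C2H2O3
pg6	C6H13O10P
ru5p	C5H11O8P
x5p	C5H11O8P
r5p	C5H11O8P
s7p	C7H15O10P
e4p	C4H9O7P
kdpg	C6H11O9P
glyc	C3H8O3
glyc_ext	C3H8O3
dha	C3H6O3
g3p	C3H9O6P
co2	CO2
co2_ext	CO2
nh3	NH3
nh3_ext	NH3
h2	H2
o2	O2
o2_ext	O2
pi_ext	H3O4P
h2o_ext	H2O
# -- screened products -------------------------------------------------
pdo13	C3H8O2
pdo12	C3H8O2
hp3	C3H6O3
bdo23	C4H10O2
bdo14	C4H10O2
ppa	C3H6O2
but	C4H8O2
adi	C6H10O4
lys	C6H14N2O2
dap	C5H14N2
ipr	C5H8
poh	C3H8O
asp	C4H7NO4
gaba	C4H9NO2
paba	C7H7NO2
phba	C7H6O3
btoh	C4H10O
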