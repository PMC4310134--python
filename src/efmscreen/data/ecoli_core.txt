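# Anaerobic E. coli core carbon network (main network: 57 metabolites,
# 75 reactions of which 24 reversible).
#
# Pathways covered: glycolysis (Embden-Meyerhof-Parnas), Entner-Doudoroff,
# pentose phosphate pathway, TCA cycle, glyoxylate shunt, anaplerotic
# reactions, anaerobic fermentation branches, glycerol degradation, the
# electron transport chain (quinone pool, fumarate respiration), both
# transhydrogenases, and import/export reactions.  Water, phosphate and
# protons are environment species (suffix _ext) and are not balanced.
# Proton translocation is folded into ATP stoichiometry at 3 H+ per ATP:
# NADH dehydrogenase I pumps 4 H+ per NADH (4/3 ATP), the membrane
# transhydrogenase consumes 1 H+ (1/3 ATP) per transhydrogenation, and the
# terminal oxidase coupling (R59, aerobic reference only) is calibrated to
# 1/2 ATP per quinol against the aerobic biomass yield ceiling.
#
# R1 is the biomass equation: precursor drains in mmol per g dry weight
# (42.56 C-mmol per g), ATP and NADPH demand, net NADH release.  The
# growth-associated ATP demand is calibrated so that the maximum anaerobic
# biomass carbon yield on glucose without electrical enhancement is 26.5%.

# -- biomass -----------------------------------------------------------
R1: 0.205 g6p + 0.071 f6p + 0.898 r5p + 0.361 e4p + 0.129 gap + 1.496 pg3 + 0.519 pep + 2.833 pyr + 3.748 accoa + 1.787 oaa + 1.079 akg + 8.512 nh3 + 3.547 nad + 18.225 nadph + 64.52 atp -> biomass + 3.547 nadh + 18.225 nadp + 64.52 adp + 64.52 pi_ext | irrev | biomass

# -- glucose uptake and glycolysis ------------------------------------
R2: glc + pep -> g6p + pyr | irrev | core
R3: g6p -> f6p | rev | core
R4: f6p + atp -> fbp + adp | irrev | core
R5: fbp + h2o_ext -> f6p + pi_ext | irrev | core
R6: fbp -> dhap + gap | rev | core
R7: dhap -> gap | rev | core
R8: gap + nad + pi_ext -> bpg + nadh | rev | core
R9: bpg + adp -> pg3 + atp | rev | core
R10: pg3 -> pg2 | rev | core
R11: pg2 -> pep + h2o_ext | rev | core
R12: pep + adp -> pyr + atp | irrev | core
R13: pyr + atp + h2o_ext -> pep + amp + pi_ext | irrev | core
R14: atp + amp -> 2 adp | rev | core

# -- anaplerosis ------------------------------------------------------
R15: pep + co2 + h2o_ext -> oaa + pi_ext | irrev | core
R16: oaa + atp -> pep + co2 + adp | irrev | core
R17: mal + nad -> pyr + co2 + nadh | irrev | core
R18: mal + nadp -> pyr + co2 + nadph | irrev | core

# -- pyruvate metabolism and fermentation branches --------------------
R19: pyr + nad -> accoa + co2 + nadh | irrev | core
R20: pyr -> accoa + for | irrev | core
R21: accoa + adp + pi_ext -> ac + atp | rev | core
R22: ac + atp -> accoa + amp + pi_ext | irrev | core
R23: accoa + 2 nadh -> etoh + 2 nad | rev | core
R24: pyr + nadh -> lac + nad | rev | core
R25: pyr + q + h2o_ext -> ac + co2 + qh2 | irrev | core
R26: for -> co2 + h2 | irrev | core
R27: h2 + q -> qh2 | irrev | core

# -- TCA cycle and glyoxylate shunt -----------------------------------
R28: accoa + oaa + h2o_ext -> cit | irrev | core
R29: cit -> icit | rev | core
R30: icit + nadp -> akg + co2 + nadph | rev | core
R31: akg + nad -> succoa + co2 + nadh | irrev | core
R32: succoa + adp + pi_ext -> succ + atp | rev | core
R33: succ + q -> fum + qh2 | rev | core
R34: fum + h2o_ext -> mal | rev | core
R35: mal + nad -> oaa + nadh | rev | core
R36: icit -> succ + glx | irrev | core
R37: glx + accoa + h2o_ext -> mal | irrev | core

# -- pentose phosphate and Entner-Doudoroff pathways ------------------
R38: g6p + nadp -> pg6 + nadph | irrev | core
R39: pg6 + nadp -> ru5p + co2 + nadph | irrev | core
R40: ru5p -> x5p | rev | core
R41: ru5p -> r5p | rev | core
R42: x5p + r5p -> s7p + gap | rev | core
R43: s7p + gap -> e4p + f6p | rev | core
R44: x5p + e4p -> f6p + gap | rev | core
R45: pg6 -> kdpg + h2o_ext | irrev | core
R46: kdpg -> pyr + gap | irrev | core

# -- membrane transhydrogenase (proton-gradient driven, 1 H+ = 1/3 ATP) --
R47: nadh + nadp + 1/3 atp + 1/3 h2o_ext -> nad + nadph + 1/3 adp + 1/3 pi_ext | irrev | core

# -- glycerol degradation ---------------------------------------------
R48: glyc + nad -> dha + nadh | rev | core
R49: dha + pep -> dhap + pyr | irrev | core
R50: glyc + atp -> g3p + adp | irrev | core
R51: g3p + q -> dhap + qh2 | irrev | core
R52: dhap + nadh -> g3p + nad | rev | core
R53: g3p + h2o_ext -> glyc + pi_ext | irrev | core

# -- electron transport chain and redox housekeeping ------------------
R54: nadh + q + 4/3 adp + 4/3 pi_ext -> nad + qh2 + 4/3 atp + 4/3 h2o_ext | irrev | core
R55: nadh + q -> nad + qh2 | irrev | core
R56: for + q -> co2 + qh2 | irrev | core
R57: mal + q -> oaa + qh2 | irrev | core
R58: lac + q -> pyr + qh2 | irrev | core
R59: qh2 + 1/2 o2 + 1/2 adp + 1/2 pi_ext -> q + 1/2 atp + h2o_ext | irrev | core
R60: nadph + nad -> nadp + nadh | irrev | core

# -- exchange reactions -----------------------------------------------
R61: glc_ext -> glc | irrev | exchange
R62: glyc_ext -> glyc | irrev | exchange
R63: fum_ext -> fum | irrev | exchange
R64: o2_ext -> o2 | irrev | exchange
R65: nh3_ext -> nh3 | irrev | exchange
R66: co2 -> co2_ext | irrev | exchange
R67: h2 -> | irrev | exchange
R68: ac -> | irrev | exchange
R69: etoh -> | irrev | exchange
R70: lac -> | irrev | exchange
R71: for -> | irrev | exchange
R72: succ -> | irrev | exchange
R73: mal -> | irrev | exchange
R74: pyr -> | irrev | exchange
R75: biomass -> | irrev | exchange
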