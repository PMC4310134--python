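# Methods

## Model

The model is a single-compartment stoichiometric description of anaerobic
*E. coli* central carbon metabolism: glycolysis, the Entner–Doudoroff and
pentose-phosphate pathways, the TCA cycle with the glyoxylate shunt,
anaplerotic reactions (PEP carboxylase/carboxykinase, both malic enzymes),
the fermentation branches (acetate, ethanol, lactate, formate/H2,
succinate), glycerol degradation (glycerol dehydrogenase with the
PEP-dependent dihydroxyacetone kinase, plus glycerol kinase), the
electron-transport chain around a quinone pool with fumarate as the
anaerobic terminal acceptor, both transhydrogenases, and import/export
reactions.  The packaged network has 57 metabolites and 75 reactions (24
reversible).  All stoichiometric coefficients are exact rationals.

Assumptions and conventions:

* **Steady state only.**  No kinetic, thermodynamic or regulatory
  constraints; computed yields are stoichiometric ceilings and real
  fermentations will fall below them.
* **Water, protons and phosphate are environment species** and are not
  balanced; element-balance validation enforces carbon (and nitrogen)
  conservation on every core and production reaction.
* **Proton translocation is folded into ATP stoichiometry** at 3 H+ per
  ATP: NADH dehydrogenase I pumps 4 H+ per NADH (4/3 ATP), the membrane
  transhydrogenase consumes 1 H+ (1/3 ATP equivalent) per NADH-to-NADPH
  transhydrogenation, the soluble transhydrogenase runs NADPH-to-NADH
  without coupling.
* **CO2 exchange is export-only.**  Carboxylation (PEP carboxylase) can
  re-fix CO2 released inside the network, but net CO2 fixation from the
  environment is not available; without this restriction a cathode could
  push product carbon yields past 100%, which is not a behaviour the
  screen is meant to describe.
* **Glucose enters by the PEP-dependent phosphotransferase system** and
  there is no ATP-dependent glucokinase bypass.  The PEP coupling of
  uptake is what keeps the ATP-coupled cathodic propanediol ceiling below
  100%; with a glucokinase route the ceiling rises to 100% and the
  reference value cannot be reproduced.
* **No maintenance ATP demand** beyond the growth-associated ATP of the
  biomass equation; ATP surpluses are dissipated by futile cycles already
  present in the network (e.g. PEP synthetase/pyruvate kinase).

### Biomass equation

Biomass formation (reaction R1) drains eleven precursors (G6P, F6P, R5P,
E4P, GAP, 3PG, PEP, pyruvate, acetyl-CoA, OAA, 2-oxoglutarate) in standard
*E. coli* proportions (42.56 C-mmol per g dry weight), consumes NADPH
(18.225 mmol/g) and ammonia, releases NADH (3.547 mmol/g), and consumes
growth-associated ATP.  The ATP coefficient is the one deliberately free
parameter of the biomass equation: it is calibrated so that the maximum
anaerobic biomass carbon yield on glucose without electrical enhancement
is 26.5%, giving 64.52 mmol ATP per g dry weight.  Biomass carbon yields
use the C-mol content of the precursor drain, on the same carbon-percent
scale as the products.

### Electrode scenarios

Electrons are an internal pseudo-species exchanged without bound with the
electrode (the soluble mediator cycle is collapsed into this exchange);
they travel in pairs, one NAD(H) per two electrons.

| scenario | reaction | ATP coupling |
|----------|----------|--------------|
| Cat1 | 2 e⁻ + NAD⁺ → NADH | +2/3 ATP per NADH (1 H+ influx per e⁻, 3 H+/ATP) |
| Cat2 | 2 e⁻ + NAD⁺ → NADH | none |
| An1  | NADH → NAD⁺ + 2 e⁻ | +4/3 ATP per NADH (2 H+ pumped per e⁻, calibrated) |
| An2  | NADH → NAD⁺ + 2 e⁻ | none |

The An1 pumping stoichiometry and the aerobic terminal-oxidase coupling
are not fixed by first principles; `calibrate_energetics` grid-searches
rationals with denominators up to 6 against two anchor biomass yields
(glucose/An1 64.1%, glucose/aerobic 71.5%) and lands on 2 H+ per electron
and 1/2 ATP per quinol, both within 1 percentage point of the anchors
(63.55% and 71.76%).  These are the packaged defaults; all coupling
parameters can be overridden per run (`eet.protons_per_electron`,
`eet.protons_per_atp`, `eet.an1_pumping`, `etc.aerobic_po`).

### Production pathways

Each of the 20 screened products is attached as a single condensed
reaction from its core precursor(s), with cofactor stoichiometry chosen
from standard biochemistry so that carbon and available electrons balance
(the per-product provenance is recorded in `efmscreen.products`).  For
example 1,3-propanediol is reached from glycerol with one NADH
(dehydratase + oxidoreductase); from glucose the route runs
DHAP → glycerol-3-P → glycerol, so each diol costs half a glucose, two
NADH and one high-energy phosphate — which is why its ceiling responds to
*both* cathodic electrons and cathodic ATP.

## Yield analytics

For a mode `v`, the carbon yield of product P from substrate S is
`100 · (flux_P · carbon_P)/(flux_S · carbon_S)`; the *top mode* is the
mode attaining the maximum (ties broken toward fewer by-product species,
then lexicographic support).  The growth-coupled maximum restricts to
modes with positive biomass flux.  By-product spectra are carbon
fractions of all secreted species relative to total carbon uptake and sum
to 100% exactly.  The degree of reduction of C_aH_bO_cN_dS_eP_f is
`(4a + b − 2c − 3d + 6e + 5f)/a`, returned as an exact rational.

Because per-scenario ceilings are maxima over a cone that *contains* the
unenhanced behaviours, adding an electrode reaction can never lower an LP
ceiling; scenario-specific summaries that can legitimately fall below the
unenhanced value (e.g. a cathodic biomass ceiling) therefore refer to the
modes that actively use the electrode, and are computed from enumerated
mode sets, not from the LP.

## Elementary-mode engine

Enumeration follows the double description method on the flux cone after
splitting reversible reactions:

1. **Compression.**  Dead-end metabolites and enforced-zero columns are
   pruned; metabolites with a single producer and single consumer are
   lumped.  Compression is mode-set preserving and fully reversed when
   folding modes back.
2. **Constraints.**  The stoichiometric equalities are reduced to an
   independent row set (exact RREF); rows are processed in an adaptive
   order that minimizes the number of candidate ray pairs.
3. **Adjacency.**  New rays come only from adjacent pairs, decided by the
   combinatorial test (no third ray's support inside the pair's support
   union) after a rank-based candidate filter (an adjacent pair spans a
   2-face, so its support union has at most `processed + 2` nonzeros);
   the tests run vectorized over bit-packed supports.
4. **Folding.**  Rays are folded to the original reaction space,
   forward/backward two-cycles are dropped, duplicates removed, and modes
   normalized (substrate uptake = 1 where the mode consumes the chosen
   substrate, else smallest positive flux = 1) and sorted
   deterministically (support, then lexicographic flux).

All arithmetic on rays is exact (arbitrary-precision integers with GCD
reduction): elementarity is a combinatorial property and floating-point
tolerances would corrupt supports.  Floats appear only in the constraint
ordering heuristic (where an error costs time, not correctness) and in
reporting.  Elementarity of any candidate vector can be checked
independently via the rank test (nullity of S restricted to the support
equals 1), which is also how the exhaustive brute-force oracle in
`efmscreen.synth` recognizes modes.

A configurable ceiling on the intermediate ray count guards against
combinatorial blow-up; exceeding it raises rather than truncates.

## LP oracle

Maximum yields are independently computed as linear programs (HiGHS):
substrate uptake fixed to 1, product export maximized.  The optimal
support is then re-solved in exact rational arithmetic; when the support
determines a one-dimensional steady-state family (the generic vertex
case) the reported optimum is exact, otherwise the float optimum is
reported (constraint residuals below 1e-9).  On every network where
enumeration is run, the enumerated maximum is asserted to equal the LP
value — the two routes to the same number share no code.

## Scaled-down census networks

Full enumeration of a complete screening cell is deliberately replaced by
two documented reductions when mode-level statistics are computed:

* **lean** removes seven composite routes (pyruvate oxidase,
  acetyl-CoA synthetase, glycerol-3-P:quinone dehydrogenase,
  non-pumping NADH dehydrogenase II, formate dehydrogenase, malate:quinone
  oxidoreductase, lactate:quinone oxidoreductase), each of which is a
  non-negative combination of retained reactions.  The flux cone — hence
  every LP ceiling — is provably unchanged.
* **condensed** additionally removes side branches orthogonal to the
  screened chemistry (lactate branch, formate-hydrogen lyase and
  hydrogenase, glyoxylate shunt, Entner–Doudoroff pathway, pyruvate
  export).  This does shrink the cone, so the per-cell LP ceiling is
  asserted (not assumed) to be preserved wherever a condensed cell is
  used.  Every mode of a condensed cell is also a mode of the full
  network, so universal statements confirmed on condensed cells
  ("no mode above 50% product yield forms biomass") are checked on a
  genuine subset of the full mode set.

Condensed cells carry 1,000–2,500 modes and enumerate in seconds; the
full cells run to at least tens of thousands of modes, beyond what the
exact pure-Python engine enumerates in interactive time, and their maxima
are obtained from the LP oracle instead.

## Synthetic fixtures

`efmscreen.synth` generates small random networks (up to 14 reactions,
always with at least one uptake and one secretion, connected, from a
fixed Mersenne–Twister recipe so fixtures are bit-stable across
platforms) together with ground-truth mode sets by exhaustive support
enumeration.  These fixtures exercise completeness and soundness of the
engine, the mode invariants, and LP/EFM agreement.  They emulate nothing
biological — no realistic degree distributions, no cofactor structure —
so passing them certifies the algorithms, not the biology; the biological
content is tested separately against the packaged network's anchor
yields.

## Known limitations

* The packaged network is a reconstruction of the described core
  metabolism, not a transcription of a deposited model; reaction-level
  choices are pinned by the printed anchor yields where available.  The
  headline product ceilings reproduce the reference values to their
  quoted precision, but quantities that are sensitive to the exact biomass
  cofactor stoichiometry deviate: the ATP-coupled cathodic biomass yield
  on glucose comes out at 28.5% (reference 32.5%), anaerobic biomass on
  glycerol without enhancement is infeasible in the product-free core
  (reference 10.0%, reachable only through NADH-consuming production
  branches), and growth-coupled product maxima run below the reference
  figures (e.g. propionate/Cat1 80.7% vs 97.7%) because the calibrated
  growth ATP demand is comparatively high.
* Elementary-mode *counts* are hypersensitive to reaction-level
  modelling choices; they are reported but never asserted.
* No thermodynamics, kinetics, regulation, mediator electrochemistry,
  electrode potentials or coulombic efficiencies — yields are ceilings.
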