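# efmscreen

Stoichiometric screening of **electro-fermentation**: which microbial
production processes would benefit from exchanging electrons with an
electrode, and by how much?

In anaerobic fermentation the achievable yield of a product is bounded by
the cell's redox (NADH/NAD+) and energy (ATP) balances.  A cathode can
inject electrons into the metabolism (raising NADH availability, with or
without concomitant ATP synthesis), and an anode can drain surplus NADH
(again with or without energy conservation).  `efmscreen` models an
anaerobic *E. coli* core carbon network with pluggable electrode
electron-transfer scenarios and computes, for every substrate x product x
scenario combination, the maximum theoretical carbon yield

```
Yield_P [%] = 100 · (flux_P · carbon_P) / (flux_S · carbon_S)
```

over **all** steady-state behaviours of the network — not just one optimal
flux distribution.  The complete behaviour set is obtained by elementary
flux mode (EFM) analysis: the EFMs are the minimal-support steady-state
flux vectors (`S·v = 0`, irreversibilities respected), they generate every
feasible flux distribution, and the screening statistics (maximum yields,
growth-coupled maxima, by-product spectra, mode censuses) are read off
them directly.

The package provides

* **`efmscreen.network`** — exact-rational stoichiometric network model,
  a plain-text reaction-table format, element-balance validation, and the
  packaged anaerobic core network (57 metabolites, 75 reactions of which
  24 reversible) with 20 condensed production pathways;
* **`efmscreen.eet`** — the four electrode scenarios: `Cat1` (cathodic
  NADH + 2/3 ATP per NADH from charge-balancing proton influx through a
  3 H+/ATP synthase), `Cat2` (cathodic NADH only), `An1` (anodic NADH sink
  through the proton-pumping respiratory chain, calibrated), `An2` (anodic
  NADH sink only);
* **`efmscreen.efm`** — a from-scratch EFM enumeration engine: double
  description over the split flux cone in exact integer arithmetic, with
  mode-set-preserving network compression and a combinatorial adjacency
  test;
* **`efmscreen.lp`** — an independent linear-programming oracle for the
  yield ceilings (by cone theory the LP optimum equals the maximum over
  the EFMs);
* **`efmscreen.screen`** — degree of reduction, carbon yields, top modes,
  growth-coupled maxima, by-product spectra, mode censuses, scatter
  tables and the full screen report;
* **`efmscreen.synth`** — random small networks with exhaustive
  brute-force ground-truth mode sets, used to verify the engine.

## Worked example

Anaerobic 1,3-propanediol production from glucose with an ATP-coupled
cathode (scenario `Cat1`), on the condensed census network:

```
$ efmscreen yield --substrate glucose --product 1,3-PDO --scenario Cat1 --efms --condensed
LP max yield: 92.86 %
1928 modes; EFM max 92.86 %; growth-coupled 49.94 %
```

Reading: with cathodic electrons *and* the ATP they bring, at most 92.86%
of the glucose carbon can end up in 1,3-propanediol (up from 57.14%
without electrical enhancement, and 62.50% if the cathode supplies NADH
but no ATP); the cell's 1928 elementary modes confirm the LP ceiling, and
the best mode that still forms biomass reaches 49.94%.  The same product
from glycerol reaches 100% on a cathode — a "true catalysis" mode with no
by-products at all:

```
$ efmscreen yield --substrate glycerol --product 1,3-PDO --scenario Cat1 --efms --condensed
LP max yield: 100.00 %
1437 modes; EFM max 100.00 %; growth-coupled 91.84 %
```

The full screen (2 substrates x 20 products x 5 scenarios, ~5 s) and the
electrode-benefit classification per product:

```
$ efmscreen screen --substrates glucose,glycerol --products all \
      --scenarios none,Cat1,Cat2,An1,An2 --out-dir out/
200 cells -> out (0 cell errors)
```

`out/screen.tsv` then contains one row per cell, e.g. 2,3-butanediol from
glucose capped at 44.44% anaerobically but 66.67% with either anode, and
flagged `anode`, while its isomer 1,4-butanediol is flagged `cathode`.

Energetic parameters that first principles leave open are calibrated
against anchor yields (see `docs/methods.md`):

```
$ efmscreen calibrate
An1 pumping: 2 H+/e-
aerobic P/O-equivalent: 1/2 ATP/quinol
worst deviation: 0.55 pp (within tolerance)
```

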