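# lakeredox

Biogeochemical analysis of a seasonally stratified lake water column:
a 1D redox reactive-transport model extended with nitrate-coupled
sulfide and methane oxidation, calibrated jointly to water chemistry and
functional-gene depth profiles, plus the abundance-and-taxonomy metric
that links 16S OTUs to metagenome-assembled genomes (MAGs), and in-silico
process-knockout experiments.

## The scientific problem

Shotgun metagenomes from stratified lakes routinely recover genomes of
sulfur- and methane-oxidizing denitrifiers, yet classical lake redox
models only couple denitrification to organic matter and iron.  This
package asks, quantitatively: if sulfide- and methane-driven
denitrification

    5 HS⁻ + 8 NO₃⁻ + 3 H⁺ → 5 SO₄²⁻ + 4 N₂ + 4 H₂O
    5 CH₄ + 8 NO₃⁻ + 8 H⁺ → 5 CO₂ + 4 N₂ + 14 H₂O

are active in the water column, can a transport-reaction model
constrained by both chemistry and marker-gene distributions accommodate
them, and what would removing them do to the ecosystem?

Four analyses, each importable from `src/` and driven by a numbered
script under `analysis/`:

1. **Reaction network** (`lakeredox.reaction_network`) — 14 redox and
   precipitation processes with dual-Monod kinetics, balanced exactly
   (rational arithmetic) over element and charge conservation;
   `balance_minimal` re-derives any stoichiometry from conservation
   alone.
2. **Lake model** (`lakeredox.lake_model`) — method-of-lines integration
   of ∂C/∂t = ∂z(D ∂z C) + Σ ν·R(C) on a 23 × 1 m column with two-layer
   turbulent diffusivity, oxygen-saturated surface and sediment sources
   of CH₄, NH₄⁺, Fe²⁺, HS⁻ and organic matter.
3. **Gene-constrained calibration** (`lakeredox.gene_mapping`,
   `lakeredox.calibration`) — marker genes (pmoABC, dsrAB, nosDZ,
   mxaCGKL, hao, iron-reduction genes) are mapped to the summed rates of
   the processes their enzymes mediate; the objective is the average
   mean absolute error (MAE) between L1-normalised observed and modelled
   profiles; the optimiser is a stochastic sequential search — truncated
   Gaussian sampling within literature bounds, an F-test picks the most
   sensitive parameter each round and fixes it at its best-fitting
   value, finished with a bounded L-BFGS-B polish.
4. **Community linking & knockouts** (`lakeredox.community`,
   `lakeredox.scenario`) — MAG abundance Aⱼ = Σ lᵢcᵢⱼ / Σ lᵢ from contig
   length × coverage, dual-axis L1 normalisation, and the combined score
   m = ‖a_OTU − a_MAG‖₂ − f (f = fraction of matching taxonomy ranks;
   m = −1 is a perfect match) with the acceptance threshold trained on
   known-correct control pairs; knockout/sweep experiments zero selected
   rate constants and compare depth-and-time-summed concentrations.

No field or sequencing data ship with the package:
`lakeredox.synthetic` generates seed-reproducible chemistry casts, gene
tables and planted OTU↔MAG communities from a known truth, so every
claim is testable end to end.

## Worked example

```sh
$ python analysis/05_knockout_and_sweep.py
```

prints (abridged):

```
knockout of sulfide_ox_no3, methane_ox_no3
species  percent_change
   NO3-       18.436487
   Fe3+       18.082303
   Fe2+       -2.191596
    HS-        2.222278
    CH4        1.261152
  SO42-       -1.409239

oxidized nitrogen (NO3-) change: +18.4% (does not decrease when its sinks are removed)
oxidized iron (Fe3+) change: +18.1%

sweep over 60 draws: Fe3+ change mean 36% (min 6%, max 84%)
```

Removing the two nitrate-coupled oxidations leaves more nitrate in the
column (+18%), and — because those processes compete with iron oxidation
for nitrate — increases the oxidized-iron inventory as well.  The sweep
repeats the comparison across uniform rate-constant draws within the
calibration bounds to show the sign of the effect is robust, not an
artefact of one parameter point.

`analysis/04_calibrate_to_genes.py` runs the parameter-recovery
experiment: four hidden rate constants, noise-free synthetic
observations, and the sequential search recovers each to within a
fraction of a percent (burn-in median objective 0.018 falling to ~1e-7
after the polish in the shipped configuration).

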