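# Methods

## The transport-reaction model

The water column is a vertical stack of `n_cells` uniform cells
(default 23 cells × 1 m, matching a ~23 m lake sampled at 1–2 m
intervals), depth increasing downward with cell centres at
(i + ½)·dz.  Each dissolved species obeys

    ∂C_s/∂t = ∂/∂z( D(z) ∂C_s/∂z ) + Σ_r ν_{s,r} R_r(C)

with turbulent diffusivity D defined on cell interfaces.  The default D
is two-layer: 50 m² d⁻¹ above the 8 m thermocline and 0.2 m² d⁻¹ below
it, so the epilimnion homogenises in hours while the hypolimnetic
mixing time (L²/D ≈ 10³ d) far exceeds a stratified season — the
regime the analysis assumes.  Boundary conditions are a fixed
oxygen-saturated surface (300 µM O₂; CH₄, HS⁻ and NH₄⁺ clamped to 0 at
the surface as an outgassing/oxidation proxy) and constant sediment
influxes of CH₄, NH₄⁺, Fe²⁺, HS⁻ and organic matter at the bottom.
These reproduce the observed shape of stratified-lake profiles —
reduced species accumulating at depth — without a sediment diagenesis
model.

The process set has 14 reactions: aerobic heterotrophy, heterotrophic
denitrification, iron reduction, sulfate reduction, methanogenesis,
nitrification, methane oxidation with O₂ and with SO₄²⁻, sulfide and
iron oxidation with O₂, iron oxidation with NO₃⁻, the two added
chemolithotrophic pathways (sulfide- and methane-driven
denitrification), and a first-order precipitation sink for reduced
sulfur (a proxy for FeS/pyrite/organic-S formation; its product is an
immobile tracked species so sulfur budgets close).  Organic matter is
proxied by CH₂O.  Every stoichiometry is balanced exactly over element
and charge conservation in rational arithmetic; `balance_minimal`
solves the conservation nullspace (sympy, exact rationals) and requires
a one-dimensional positive solution, returning coprime integer
coefficients.  H⁺ and H₂O appear in the stoichiometries so that balance
is exact but are excluded from the transported state: pH and the water
budget are not modelled.

Kinetics are dual-Monod with optional oxygen inhibition on the
anaerobic processes,

    R = k · [D]/(K_D+[D]) · [A]/(K_A+[A]) · K_I/(K_I+[O₂]),

expressed per mole of electron donor; k is in µM y⁻¹ (the precipitation
constant in y⁻¹, first-order in HS⁻).  The original model family this
column model generalises does not publish its exact rate forms;
dual-Monod is the standard choice and is declared as an assumption.
Half-saturation constants default to typical freshwater values
(K_O₂ ≈ 8 µM, K_NO₃ ≈ 10 µM, K_SO₄ ≈ 100 µM, K_CH₄ ≈ 20 µM,
K_OM ≈ 50 µM, K_I = 5 µM); maximum rates were set once so that the
default 180-day season develops the canonical redox zonation (oxygen
confined above the thermocline; Fe²⁺, HS⁻ and CH₄ maxima at the
sediment).

Integration is method-of-lines with LSODA (stiffness-switching) on a
cell-major state ordering, which makes the Jacobian banded with
bandwidth = number of species; relative tolerance defaults to 1e-6.
Concentrations are clipped at zero in saved outputs with the clipped
mass logged; rates are evaluated on concentrations floored at zero.
Closed-column runs conserve S, N, Fe and C inventories to within the
solver tolerance (this is asserted over random sub-networks in the test
suite).  Process rates are reported in µM y⁻¹ (×365 from the internal
day unit).  `column_total` sums concentration over cells × dz and over
saved times — on the uniform grid this midpoint rule is the natural
discrete column inventory and reproduces the worked example
(1 µM × 23 cells × 5 times = 115).

## Gene profiles and the calibration objective

Marker-gene counts are normalised per sample to copies per million
(CPM) and then L1-normalised across the depth profile of each gene, so
a profile carries only distributional information.  Under the
proportionality assumption — a gene's relative depth distribution
tracks the relative rates of the processes its enzymes mediate — the
modelled counterpart is the L1-normalised sum of mapped process-rate
fields, interpolated linearly in depth at the nearest saved time.  The
default map: pmoABC → nitrification + CH₄ oxidation with O₂ and SO₄²⁻
(the particulate monooxygenase co-metabolises ammonia and methane);
dsrAB → sulfate reduction + sulfide oxidation with every acceptor
(forward and reverse operation); nosDZ → heterotrophic plus autotrophic
denitrification, where autotrophic denitrification in this extended
network comprises all three lithotrophic nitrate-reducing pathways
(Fe²⁺-, HS⁻- and CH₄-driven) — the genomes motivating the added
processes carry nosZ; mxaCGKL → methane oxidation; hao → nitrification;
iron-reduction genes → heterotrophic iron reduction.

The fit metric is the unweighted average of per-observable mean
absolute errors: one MAE per chemistry (species, time) profile and one
per gene set.  Chemistry profiles are L1-normalised per profile before
the MAE so chemistry and gene observables share the [0, 1] scale of
relative distributions; whether the original analysis normalised
concentrations is not documented, and the normalised choice is the one
on which MAE values of ~0.2 are plausible.  A configurable weight
vector is provided; the default is unweighted.

## The sequential stochastic search

Each free parameter carries literature bounds, a Gaussian centre and
width (defaults: mid-bounds, ¼ of the bound width).  Per iteration, m
parameter vectors are drawn from truncated Gaussians (rejection
resampling, so no probability atoms at the bounds; m defaults to 200
and is configurable), the objective is evaluated for each, and each
free parameter gets a univariate regression F-test
(F = (m−2)R²/(1−R²), p from F(1, m−2)) of objective on parameter.
After a burn-in round that only re-centres, each iteration fixes the
lowest-p (most sensitive) parameter at its value in the best-scoring
sample of that iteration; p ties break by specification order.  Centres
of the remaining Gaussians move downhill by the standardised
sensitivity, Δ = σ·(slope·σ/sd(objective)), clipped to bounds; the next
width is the distance moved, floored at 2% of the bound width so
sampling never degenerates.  The exact re-centring formula is not
published and this rule is a declared design choice.  The linear
F-test screen is blind to a parameter whose optimum coincides with the
sampling centre (zero linear trend through a symmetric minimum) — an
inherent property of the published screen, visible in the test design.

Once every parameter is fixed, L-BFGS-B refines the point within
bounds.  The polish optimises in unit-box coordinates (each parameter
mapped to [0,1] by its bounds): the parameters span orders of
magnitude, and a gradient-norm stopping rule is only meaningful on a
common scale.  Gradients are central differences with step 1e-6 of the
bound width, one-sided at an active bound so the objective is never
evaluated outside the box.  The returned point never scores worse than
its start.  The whole search is driven by one integer seed and is
bitwise reproducible.

## OTU–MAG linking

MAG abundance in sample j is the length-weighted mean contig coverage
A_j = Σ l_i c_ij / Σ l_i, divided by the library read count.  OTU and
MAG tables are L1-normalised along both axes, within samples (columns)
first and then within features (rows); tables are subset to the shared
samples before normalising.  For a candidate pair, f is the fraction of
the MAG's assigned kingdom-to-genus ranks the OTU matches — ranks
compared independently, the MAG taxonomy as denominator — and the
combined score is m = ‖a_OTU − a_MAG‖₂ − f.  On dual-L1 rows the
Euclidean term is bounded by √2, so m ∈ [−1, √2]; the reported range of
[−1, 1] in field data is an empirical observation, not a clamp, and
m = −1 holds exactly iff the rows are identical and f = 1.  RDP-style
fixed-rank taxonomy is filtered before use: ranks with confidence below
50% or named *Incertae Sedis* become unassigned, each rank
independently.

The acceptance threshold is trained on known-correct control pairs as
the smallest tolerance admitting all of them (the maximum control
score), separately per dataset, and a pair is accepted only if it
passes in both the amplicon-derived and metagenome-derived OTU
dataset.  Assignment is greedy one-to-one by ascending amplicon score
with lexicographic tie-breaks (a many-to-one flag disables the
one-to-one constraint).  Gene-content clustering of features uses
complete linkage on 1 − Spearman ρ.

## Knockouts and sweeps

A knockout zeroes the maximum rate constants of the listed processes
and re-runs the otherwise identical scenario; the response variable is
each species' concentration summed over all depths and saved times,
reported as percent change against the baseline run (species with a
zero baseline inventory are reported as undefined rather than 0%).
The sweep repeats the comparison over uniform draws of the rate
constants within their calibration bounds; draws are seeded, failed
simulations are logged and excluded, and more than 10% failures aborts
the sweep.  Whether the original analysis re-calibrated per draw is not
stated; pure sampling is implemented.

## Synthetic data: what it emulates and what it does not

`make_scenario` draws "true" values for the free rate constants
log-uniformly inside the calibration bounds (kept a factor 1.5 off the
edges) and runs the default season.  `make_observations` samples the
run at 2 m intervals with multiplicative lognormal noise (σ in log
space; default 0.1); `make_gene_tables` perturbs the noise-free gene
proxies the same way and renormalises, so at zero noise the generated
tables close the loop with the objective exactly.  `make_community`
plants 12 populations as Gaussian depth bumps observed through three
channels over 11 shared samples: multinomial counts at 50 000 reads per
sample (amplicon), per-feature lognormal noise (metagenome-derived
OTUs, default σ = 0.2), and 3–10 contigs per MAG whose coverages carry
independent lognormal noise.  50 extra OTUs have no MAG partner.
Planted pairs share the MAG's assigned taxonomy; a quarter of MAGs are
classified only to family (genus unassigned), as is typical of
contig-based classification — a deliberately *correct* partial path,
since a known-correct pair with contradictory taxonomy would
contradict its own premise.  Eight pairs are flagged as controls for
tolerance training.

Because the trained tolerance is the maximum of the control scores, a
held-out true pair is covered with probability n_controls/(n_controls+1)
per dataset under exchangeable noise — an order-statistics property of
the published training rule itself.  Recovery is therefore evaluated as
a rate pooled over replicated communities (the test suite pools 30),
where the default configuration recovers ≥95% of planted pairs with no
false acceptances of partner-less OTUs.

The generators emulate the statistical structure the analysis relies
on — co-varying abundance across two library types, shallow/partial
taxonomy, depth-structured gene signal proportional to summed rates —
and none of the things it does not: no sequence content, chimeras,
contamination, copy-number variation, or compositional artefacts of
real libraries.  Passing tests therefore demonstrate correctness of the
procedures under their own assumptions, not performance on real lake
data.

## Problem sizes and numerical defaults

Documented desk-scale sizes used by the shipped drivers and tests, all
chosen as the smallest sizes at which each property is cleanly
measurable: 23-cell column, 180-day season saved every 45 days;
simulation rtol 1e-6 (1e-5 inside calibration loops, where the
objective differences of interest are ~1e-2); calibration m = 200 on
cheap objectives and m = 60 with a 60-iteration polish cap on the
simulation-backed recovery experiment (4 free parameters, noise-free
observations); sweeps of tens of draws in the drivers (the procedure
itself scales to arbitrary n); 30 pooled synthetic communities for
match-recovery rates.

## Known limitations

pH, alkalinity, temperature dependence, gas ebullition, particle
settling (beyond the precipitation sink), seasonal thermocline
deepening (a static two-layer D is the default; the grid accepts any
interface profile), and microbial biomass dynamics are not modelled.
The re-centring rule and the dual-Monod forms are declared assumptions
where the source procedure is underdocumented.  Headline field-data
numbers (MAE ≈ 0.2 fits, specific knockout percentages) depend on the
unpublished lake observation set and are not reproduced; the package
reproduces the *procedures* and their exactly checkable quantities.
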