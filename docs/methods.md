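# Methods

`picoflux` implements isotopically nonstationary metabolic flux analysis
(INST-MFA) for photoautotrophs labeled by a step change of the inorganic
carbon pool to ¹³C, together with the biomass and energetics accounting
that turns a fitted flux map into a carbon- and cofactor-balanced picture
of the cell. This note records the models, the defaults and their
rationale, the numerical choices, and the limits of what the bundled
synthetic experiments can demonstrate.

## Model

### Network and atom transitions

A metabolic network is a set of reactions over compartmentalized species
(chloroplast `.h`, cytosol `.c`, mitochondria `.m`; externals `.x` are
excluded from mass balance). Every carbon-carrying reaction declares an
atom map in the lowercase-letter convention (`OAA.m (abcd) -> PEP.c (abc)
+ CO2.m (d)`); the parser enforces that each letter appears exactly once
per side, so carbon is conserved reaction by reaction. Reversible steps
are encoded as a net flux plus a nonnegative exchange flux (forward
`vf = exch + max(net,0)`, backward `vb = exch + max(−net,0)`), which is the
standard identifiable parameterization: exchange affects labeling but not
mass flow. Rotationally symmetric intermediates (succinate, fumarate) are
handled by splitting every production route into the two molecular
orientations at half flux each, which reproduces positional scrambling
downstream.

At metabolic steady state `S·v = b`, with biomass sink fluxes pinned at
the growth rate; the solution manifold is parameterized as
`v = v₀ + N·θ` through the null space, so every candidate during
optimization satisfies the balance exactly. Where possible the free
coordinates θ are chosen as the net fluxes of named anchor reactions
(here the AKG→succinate branch and the malic-enzyme shuttle), so the
parameters carry physical units and their box bounds come from a linear
program over the feasible flux polytope.

Intracellular CO₂ is a balanced species in every bundled network:
decarboxylation carbon can return to the chloroplast and be refixed,
which is what lets a high-TCA-flux regime raise its carboxylation flux
without raising net uptake. Net CO₂ uptake is consequently never an
input: it is read off the fitted solution, being fixed by the biomass
sink demands through the balance. The glyoxylate shunt is absent from
all bundled networks.

### EMU labeling dynamics

Measured fragments are simulated through a demand-driven elementary
metabolite unit (EMU) decomposition: backward traversal from each
measured fragment collects the minimal closed set of carbon-atom subsets
whose mass isotopomer distributions (MIDs) must be balanced. The
transient balances per size block are

    P_m dX/dt = Σ_r coef_r · v_r · (convolution of source MIDs) − c_m · X

with `P_m` the pool size (µmol gDW⁻¹), `c_m` the total consumption of the
species, and convolutions coupling only strictly smaller blocks. Units:
fluxes enter in mmol gDW⁻¹ h⁻¹ and are converted at the boundary by
1000/3600 µmol gDW⁻¹ s⁻¹ per unit, so the labeling time constant of a
pool is 3.6·P/v seconds.

The label input is an ideal step at t = 0 with tracer purity 0.99 and a
residual unlabeled inorganic-carbon fraction 0.05 (per-atom ¹³C
probability 0.9405 after the bolus). Both are configurable; the values
describe a well-executed bicarbonate bolus rather than gas–liquid
transfer, which is not modeled. The ≤10 s quench delay of real sampling
is likewise not modeled and is a small bias source for the fastest pools.

Two observation-model layers sit on top of the simulated MIDs: an
inactive-pool dilution fraction per measured metabolite
(`observed = (1−d)·active + d·unlabeled`), and forward natural-abundance
convolution at p¹³ = 0.0107, applied to the simulation rather than
deconvolved from the data by default so both raw and corrected workflows
are possible.

### Flux estimation

Fitting minimizes the SD-weighted sum of squared residuals (SSR) between
simulated and measured MIDs over θ, exchange ratios `r = e/(1+e) ∈ [0,1)`,
log₁₀ pool sizes (bounds 10⁻³–10³ µmol gDW⁻¹), and optional dilution
fractions, using trust-region-reflective least squares restarted from
random initial guesses (θ uniform in the LP-feasible box, pools
log-uniform). Replicate SDs of triplicates are unstable, so a floor of
0.005 mole fraction is applied. The best start wins (ties broken by start
index); goodness of fit is judged against the central 95% chi-square
interval at `df = n_observations − n_fitted_parameters` — every fitted
quantity counts. Pool-size parameters may be grouped (members share one
fitted value); the bundled configuration groups the three compartmental
CO₂ pools, which turn over in tens of milliseconds and carry no
independent labeling signal at 30 s sampling resolution.

Confidence intervals use parameter continuation: walk one parameter away
from the optimum, re-optimizing all others warm-started from the previous
point, until the SSR profile crosses `SSR_min + χ²(1, level)`; the
crossing is bracketed and bisected, since the profile is far from
quadratic along flux/pool ridges. A walk that reaches a parameter bound
reports that side as unbounded (a nonnegative flux whose lower walk ends
at 0 reports 0). Fitted flux maps are reported normalized so net CO₂
uptake is exactly 100 units, which preserves all flux ratios.

### Biomass and energetics

Measured macromolecular fractions rarely close a mass balance. The
correction applies component-specific recovery factors (FAME and
carbohydrate; default 1.0 as the study-specific values are not public)
*before* one global scaling to 100% AFDW — this order keeps the global
step a pure closure operation. Precursor demands come from an editable
monomer table (residue masses, precursor stoichiometries, carbons);
protein uses a per-strain amino-acid profile, falling back to the table's
even default with a warning. Growth rate is the least-squares slope of
ln(TOC) versus time. Demands are linear in composition, and the shipped
tables close the carbon balance by construction (demand × carbons
reproduces each class's carbon content to <1%).

The energetics ledger is linear in fluxes with one affine term: ATP
maintenance, default 2.85 mmol gDW⁻¹ h⁻¹ (a green-algal literature
value), applied to ATP only and included in the headline ratio by
default. Consumption is positive, production negative, so the
malic-enzyme shuttle's NADPH output lowers net NADPH demand. NADH is a
separate currency — no transhydrogenase is assumed — and never enters
the ATP/NADPH ratio. Per-reaction costs in the bundled table are
canonical (3 ATP + 2 NADPH per net CO₂ fixed across the carboxylation
and reduction lumps; 2 ATP + 1 NADH produced per triose in lower
glycolysis); biomass-sink costs are derived at run time from the actual
precursor demands with literature-typical polymerization costs (~4.3 ATP
per amino-acid residue, 1 ATP + 2 NADPH per C2 unit of fatty acid), since
a static per-flux cost cannot be correct across compositions. Reference
stoichiometries for comparison: linear electron flow produces ATP:NADPH
at (12 × 3/14)/2 ≈ 1.29, the Calvin–Benson–Bassham cycle consumes at
3/2 = 1.5.

### Photophysiology utilities

NPQ = (Fm − Fm′)/Fm′, scale-invariant by construction. The
single-turnover flashlet schedule uses a constant 2.5 µs excitation delay
and geometric relaxation delays jᵢ = 20 µs × 1.025ⁱ. An alternative
published power-law parameterization (10^(1.6+1.025·i) µs) is available
behind a flag but produces delays beyond any instrument's range within a
dozen flashlets, so the geometric reading is the default. Inhibitor
comparisons use a two-sided two-sample t test, Welch by default (pooling
is the documented alternative).

## Bundled networks and scenarios

Three networks ship with the package:

* **full** (38 reactions): explicit CBB with pentose-phosphate
  regeneration (TK/TA, SBPase), photorespiration, chloroplast/cytosol
  split glycolysis behind a triose-phosphate transporter, PEP transport
  for plastid fatty-acid synthesis, an incomplete-TCA mitochondrion, and
  CO₂ shuttling. Used for validation and demonstration.
* **core** (17 reactions + sinks): the fitting scenario network. CBB is
  aggregated to a C5-acceptor motif with a carbon-conserving 5 TP → 3 RuP
  regeneration lump whose atom routing is approximate — adequate for
  synthetic ground-truth studies, not for interpreting real pentose
  labeling.
* **small** (12 reactions + sinks): single-compartment variant used for
  the statistical studies (recovery, coverage, calibration), keeping the
  TG2-like topology: storage and protein sinks, anaplerosis, the
  inactive AKG→succinate branch with symmetric succinate, the
  malic-enzyme shuttle.

Scenario presets encode two contrasting carbon-partitioning regimes at
high light, with compositions and growth rates from the bundled strain
table (carbohydrate-rich: 44.9% carbohydrate at µ = 0.220 h⁻¹;
protein-rich: 50.8% protein at µ = 0.323 h⁻¹; an extreme-starch mutant at
56.1% carbohydrate). Free branch fluxes are set from the qualitative
biology: the AKG→succinate branch is effectively inactive everywhere
(10⁻⁴ mmol gDW⁻¹ h⁻¹ against a 10 µmol gDW⁻¹ succinate pool, so
succinate labels by well under 1% in 10 minutes), and the malic-enzyme
shuttle carries 1.2 mmol gDW⁻¹ h⁻¹ only in the protein-rich regime,
driving net OAA→malate flux there. Pools follow the fast-CBB/slow-amino-
acid contrast (0.05–0.4 µmol gDW⁻¹ for CBB intermediates vs 2–10 for
TCA-derived precursors), with amino-acid precursor pools reduced in the
carbohydrate-rich presets. True pool sizes for the organism are
unpublished; these are order-of-magnitude choices and only their
qualitative contrast matters to the tests.

## Synthetic data: what it does and does not emulate

The generator simulates the six-time-point (0/30/60/180/300/600 s)
triplicate design with independent Gaussian noise of SD 0.01 mole
fraction per MID entry — the scale at which triplicate LC-MS
isotopologue fractions typically scatter. By default noisy replicates
are clipped to [0,1] and renormalized so rows remain on the simplex,
mirroring how measured MIDs are intrinsically nonnegative normalized
intensities. That clipping is not innocent: for channels whose true value
is within ~2 SD of zero it injects a positive bias of up to ~0.4 SD and
the renormalization pushes the complementary deficit into M+0, which a
fitter reads as spurious labeling of otherwise unlabeled metabolites.
This is a real artifact of simplex-valued noise, not a bug, and it is the
reason the estimator-calibration studies (parameter recovery, CI
coverage, SSR calibration) run with the generator's unclipped Gaussian
mode, where the estimator's noise assumptions hold. Forward natural
abundance (p¹³ = 0.0107) is applied to all generated data, which also
keeps the informative M+1 channels well away from the clip boundary.

What passing these studies shows: the simulator is exact against an
exhaustive isotopomer oracle, the estimator recovers identifiable fluxes
from its own forward model, its confidence intervals are calibrated
under the assumed noise, and the SSR statistic is chi-square distributed
at the truth. What they do not show: robustness to the many ways real
LC-MS data violate those assumptions — correlated channel noise,
intensity-dependent variance, retention-time drift, quench-delay
label turnover, or an imperfect network model.

The near-zero branch flux is deliberately left out of the point-recovery
criterion: at sub-percent labeling depth only the rate ratio flux/pool is
informed, so the honest statement about that branch is an interval
containing zero — which is exactly how the biological finding it mirrors
("no significant flux from AKG to succinate") is phrased.

## Numerical choices

* Default transient integrator: block-sequential variable-step BDF2
  (L-stable, so millisecond-turnover pools are handled gracefully) on a
  fixed grid refined near t = 0 (~170 nodes to 600 s), with cached matrix
  inverses shared across steps and an optional JIT of the time march.
  Accuracy ~2×10⁻³ worst-case against the reference path — ample for
  fitting at noise SD 0.01, and bias-free in self-consistency studies
  because generator and fitter share the integrator.
* Reference integrator (`method="ivp"`): monolithic LSODA at rtol 1e−8 /
  atol 1e−10, used for oracle comparisons; agrees with the exhaustive
  isotopomer ODE to ≤1e−6 on all bundled toys.
* The isotopomer oracle integrates all 2^C states per species and refuses
  species above 6 carbons (configurable); it exists to verify, never to
  fit.
* Optimizer: `scipy.optimize.least_squares` (TRF, `x_scale="jac"`), 2-point
  finite-difference Jacobians; exact sensitivities are a non-goal at this
  problem size.
* Natural-abundance correction inverts the binomial convolution matrix
  and clips negatives (warn/raise configurable) before renormalizing.
* Profile walks start at 2% of parameter scale by default (the statistical
  studies use coarser 40% walks with bisection, trading CI resolution for
  runtime), doubling until the threshold brackets, then ≤6 bisections.
* Study sizes in the shipped test-suite: 50 coverage repetitions with
  single warm-started fits (coverage checks CI calibration, not global
  search, so starting at the truth is the standard protocol), 100
  SSR-calibration repetitions, 20 random starts for the noise-free
  recovery study, and the statistical studies run on the reduced
  single-compartment network.

## Known limitations

* The core and small networks aggregate CBB regeneration with
  approximate atom routing; positional isotopomer predictions for
  pentoses are not meaningful there (use the full network).
* Exchange fluxes and unmeasured pools are weakly identifiable, as in
  any INST-MFA; their intervals are honest but wide, and profile CIs on
  them can be one-sided.
* The energetics ledger ignores photosynthetic electron-transport
  details (cyclic electron flow magnitude is out of scope); it prices
  demand, not supply.
* Measured compositions that fail mass balance are closed by scaling —
  the method cannot distinguish under-recovery from real missing
  components.
* Single-element (¹³C) tracers only; no ¹⁵N, no multi-tracer designs.
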