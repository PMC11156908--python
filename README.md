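# picoflux

Isotopically nonstationary ¹³C metabolic flux analysis (INST-MFA) for
photoautotrophs, built around the transient labeling design used for
fast-growing picoalgae: a step change of the inorganic carbon pool to
¹³C-bicarbonate at t = 0, LC-MS sampling of mass isotopomer distributions
(MIDs) at 0/30/60/180/300/600 s in biological triplicates, and flux
inference before isotopic steady state is reached.

The package is for metabolic engineers and systems biologists who want to

* represent compartmentalized reaction networks with carbon atom
  transitions (chloroplast / cytosol / mitochondria, transporters,
  dilution pools, biomass sinks),
* simulate transient labeling through elementary metabolite unit (EMU)
  balances — with an exhaustive isotopomer oracle to verify against,
* estimate fluxes, pool sizes and dilution fractions by multi-start
  least squares with chi-square goodness of fit and profile-likelihood
  (parameter-continuation) confidence intervals,
* close biomass compositions to mass balance and convert them into
  precursor sink demands, and
* audit the resulting ATP/NADPH economy against the reference
  stoichiometries of linear electron flow and the CBB cycle.

## The model in brief

At metabolic steady state the net fluxes satisfy `S·v = b`, with biomass
sink fluxes pinned at µ times the precursor demand vector; candidates are
parameterized as `v = v₀ + N·θ` through the null space so the balance
holds exactly throughout optimization. Labeling obeys the transient EMU
balances per fragment `X`:

    P dX/dt = Σ_r v_r · (⊛ source MIDs) − c · X

with pool sizes `P` (µmol gDW⁻¹), total consumption `c`, and ⊛ denoting
MID convolution for condensation reactions. Reversible steps carry a net
plus a nonnegative exchange flux; symmetric metabolites scramble 50/50.
The fit minimizes the SD-weighted SSR between simulated and measured
MIDs; fit quality is judged against the central 95% chi-square range and
per-parameter intervals come from walking each parameter while
re-optimizing the rest until SSR crosses `SSR_min + χ²(1, 0.95)`. Flux
maps are reported normalized to 100 units of net CO₂ uptake — which is
itself an output of the fit, fixed by the sink demands, never an input.

## Worked example

The bundled scenarios generate complete synthetic experiments with known
ground truth. Fitting the reduced protein-rich scenario end to end:

```sh
picoflux fit --scenario tg2-small --starts 4 --seed 1 --out fit_out
```

prints (abridged):

```json
{
  "ssr_bracket": "SSR = 200.9 [148.3, 223.5]",
  "df": 184,
  "co2_uptake": 13.53,
  "normalized_co2_uptake": 100.0,
  "atp_nadph_ratio": 1.87,
  "seed": 1
}
```

Reading this: the best of 4 starts reached SSR 200.9 against 184 degrees
of freedom (198 MID observations minus 14 fitted parameters), inside the
central 95% chi-square acceptance range [148.3, 223.5] — a statistically
acceptable fit. The fitted net CO₂ uptake is 13.5 mmol gDW⁻¹ h⁻¹
(recovering the scenario's true 13.53, which the generator derived from
the protein-rich composition at µ = 0.323 h⁻¹), and the demand ledger
prices the solution at 1.87 ATP per NADPH including 2.85 mmol gDW⁻¹ h⁻¹
maintenance ATP. `fit_out/` contains the per-reaction report
(net/exchange fluxes and CO₂-normalized values), the normalized flux map,
the energy ledger, and a summary embedding the seed and config hash.

The same machinery exposes the carbon-partitioning contrast between the
bundled carbohydrate-rich (`tg1`) and protein-rich (`tg2`) regimes on the
compartmentalized core network: the normalized phosphoglucomutase
(storage) flux is ~3× higher in `tg1`, triose-phosphate export is higher
in `tg2`, the malic-enzyme shuttle runs only in `tg2`, and the
AKG→succinate branch is statistically indistinguishable from zero in
both — its profile interval always contains 0.

Library use mirrors the CLI:

```python
from picoflux import synthetic as syn
from picoflux.fit import fit_fluxes, profile_ci

scn = syn.scenario("tg2-small", seed=1)
emunet = scn.emu_network()
meas, truth = syn.generate_experiment(scn, emunet=emunet)
fit = fit_fluxes(scn.network, emunet, meas,
                 syn.scenario_fit_config(scn, starts=4, seed=1),
                 label=scn.label)
ci = profile_ci(fit, "akgsuc")   # branch flux: interval contains 0
```

Other entry points: `picoflux network validate <tsv>` (atom-balance and
feasibility report), `picoflux synth` (write a synthetic experiment plus
`.truth.json` sidecar), `picoflux simulate`, `picoflux energetics`,
`picoflux biomass correct|demands`, `picoflux npq`, and `picoflux run
--config run.yaml` for the full pipeline.

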