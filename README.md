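# n15flux

Processing library and CLI for the **¹⁵N gas-flux method**: direct field
quantification of denitrification — the microbial reduction of soil nitrate
to N₂O and N₂ — from automated static-chamber measurements on an
isotope-ratio mass spectrometer (IRMS).

Highly ¹⁵N-enriched NO₃⁻ fertilizer is applied to soil; gas produced by
denitrification of that labelled pool carries excess heavy isotopologues
(²⁹N₂/³⁰N₂ and ⁴⁵N₂O/⁴⁶N₂O) that accumulate in a closed chamber headspace
above the enormous atmospheric N₂ background. `n15flux` turns raw per-
injection ion currents (m/z 28/29/30 on the N₂ path, 44/45/46 on the N₂O
path) plus chamber metadata into N₂ and N₂O fluxes, detection limits, and
campaign-level denitrification summaries, and ships a forward simulator so
the whole chain is testable without instrument data.

## The model

Both gases carry two N atoms, so a single source pool at ¹⁵N atom fraction
*a* produces isotopologues by binomial (random) isotope pairing,

    f_light : f_mid : f_heavy = (1−a)² : 2a(1−a) : a²,

and the headspace is a two-component mixture of background gas and
pool-derived gas (fraction *d*). With background-subtracted ratio excesses
Δ (e.g. Δ²⁹R = ²⁹R_sample − ²⁹R_ambient) and x = Δ_heavy/Δ_mid, the pool
enrichment follows in closed form,

    aD = (2x(1−a_b) − a_b) / (1 − 2a_b + 2x(1−a_b)),     a_b = background ¹⁵N,

which reduces to the classical aD = 2x/(1+2x) for an unlabelled background;
the pool-derived fraction follows from Δ_heavy and aD (d ≈ Δ_heavy/aD² in
the trace-signal limit, exactly by solving the mixing model otherwise). On
the N₂O path, ¹⁷O/¹⁸O contributions to ⁴⁵R/⁴⁶R are removed by an exact
cross-term correction before inversion. Per closure, four timed samples
give a linear regression of concentration (N₂O) and of pool-derived mol
fraction (N₂ + N₂O); slopes convert to fluxes by the ideal-gas chamber
factor

    F = slope · (P·V)/(R·T) · 28.014 g N mol⁻¹ · (10⁴/A) m² ha⁻¹ · 1440 min day⁻¹,

with an r² < 0.80 discard rule, and N₂ flux = (N₂+N₂O) − N₂O. Detection
limits follow DL = t(n−1, one-sided 0.95) × SD from reference-gas
replicates, propagated to method detection limits (MDL) in flux units.

## Worked example

Simulate the reference campaign (8 chambers, two fertilizer rates of
50/100 kg N ha⁻¹ labelled at 60 atom %, 7 days, 4 samples per 201.67 min
closure, instrument noise at the reported reference-gas SDs) and process
it back:

```sh
n15flux simulate --seed 1 --out-dir sim
n15flux process --injections sim/injections.csv --chambers sim/chambers.csv \
    --out-dir out --fertilizer-enrichment 0.60
```

```
closures: 112 (accepted 108, discarded 4, below detection 0)
treatment  n_chambers  cum_n2_kgN_ha  cum_n2_se  cum_n2o_kgN_ha ...  product_ratio_of_means  n2o_d_share  aD_mean  fertilizer_fraction
     100N           4       5.413787   0.060625        0.672701 ...                0.898377     0.910358 0.479480             0.799133
      50N           4       1.997007   0.030522        0.130288 ...                0.951461     0.781944 0.459472             0.765787
```

Reading the 100 N row: over seven days the four replicate chambers lost
5.41 ± 0.06 kg N ha⁻¹ as N₂ and 0.67 kg as N₂O, of which 91% was
denitrification-derived (N₂O_d); the product ratio N₂/(N₂+N₂O_d) of 0.90
says denitrification ran almost completely to N₂; the denitrifying pool
enrichment aD ≈ 0.48 against the 0.60 fertilizer enrichment means ~80% of
the losses were fertilizer-derived. A handful of closures fail the r²
linearity check at this noise level and are discarded and gap-filled.

The `mdl` subcommand reports the instrument detection limits and their
flux-unit propagation for the configured chamber:

```sh
$ n15flux mdl
DL 30R (ratio)                      1.417e-06
DL N2O conc (ppm)                   0.0233
MDL N2 (g N/ha/day)                 54.3
MDL N2O, rounded DL (g N/ha/day)    0.25
MDL N2O, unrounded DL (g N/ha/day)  0.29
```

## Layout

- `n15flux.isotope` — isotopologue ratios, binomial pairing, mixing model and its inversion
- `n15flux.fluxes` — concentration calibration, closure regression, QC, flux conversion
- `n15flux.detection` — reference precision, DL (t × SD) and MDL propagation
- `n15flux.campaign` — daily/cumulative aggregation, product ratio, source partitioning
- `n15flux.simulate` — forward campaign simulator (configs in YAML)
- `n15flux.io` / `n15flux.pipeline` / `n15flux.cli` — CSV I/O, run orchestration, CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
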