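# Methods

## Measurement model

The ¹⁵N gas-flux method infers denitrification N₂ and N₂O emissions from
the accumulation of heavy isotopologues in a closed chamber headspace
above soil whose NO₃⁻ pool has been labelled with highly enriched
fertilizer. `n15flux` models the headspace of each gas as a two-component
mixture:

* **Background** gas at its ambient isotopic composition. For N₂ the
  background is measured ambient air (mean of the run's air-reference
  injections); in the absence of measured references the natural ¹⁵N
  abundance 0.0036630 atom fraction is used.
* **Pool-derived** gas produced from a single denitrifying NO₃⁻ pool at
  atom fraction `a`. Random isotope pairing gives binomial molecular
  fractions (1−a)², 2a(1−a), a² for the light/mid/heavy isotopologues —
  the single-pool assumption; hybrid sources (e.g. a nitrification pool at
  a different enrichment) are out of scope.

Mixing is linear in the pool-derived mol fraction `d`. Two useful exact
identities follow from the algebra: (i) the delta-ratio ratio
x = Δheavy/Δmid is independent of `d`, so the background-corrected closed
form `a = (2x(1−a_b) − a_b)/(1 − 2a_b + 2x(1−a_b))` is exact at any
mixing fraction (the textbook `2x/(1+2x)` is its unlabelled-background
limit and errs by several percent at low enrichment over a natural
background); and (ii) given `a`, the heavy-isotopologue balance yields
`d` in closed form. A fully numerical inversion (`invert_mixing`,
bracketing + Brent) is kept alongside as an independent route; tests
require the two to agree within 1% over a ∈ [0.05, 0.95],
d ∈ [10⁻⁶, 0.05], and they agree to numerical precision on
model-consistent input.

### Oxygen isotopes on the N₂O path

Measured ⁴⁵R/⁴⁶R contain ¹⁷O/¹⁸O contributions. Because the O-isotope
distribution is the same in background and pool-derived N₂O and
independent of the N isotopes, Δ⁴⁵R is already purely the N-pair delta,
and Δ⁴⁶R carries exactly one cross-term, (a₁₇/a₁₆)·Δ⁴⁵R, which
`oxygen_corrected_deltas` subtracts; `nitrogen_ratio_pair` applies the
matching correction to the background pair. This reduces the N₂O path to
the same diatomic problem as the N₂ path with no approximation, which is
why the noiseless simulator round trip is exact rather than merely
percent-accurate. The full mass-44…48 distribution (binomial ¹⁵N ×
natural ¹⁷O = 0.000379, ¹⁸O = 0.0020052) is used where it matters
physically: the IRMS monitors masses 44–46 only, so concentration
calibration against the 1 ppm standard rescales both current sums by
1/(1 − f₄₇ − f₄₈).

## Per-closure computation

Each closure yields four timed injections per path (defaults 0, 67.22,
134.45, 201.67 min of a 221.83 min closure — an even spread over the
sampling window). Per timepoint:

* N₂O path: Δ-ratios against the standard's mean ratios → (aD, d);
  concentration against the standard; pool-derived concentration d·C.
* N₂ path: Δ²⁹R/Δ³⁰R against the air background → d, using aD from the
  N₂O path of the same closure. N₂O is a trace gas so its pool-derived
  fraction (and hence signal-to-noise on aD) is far higher than on the
  N₂ path; the self-derived N₂ estimate (XN¹⁵) is the fallback when the
  N₂O path is below detection.

The closure enrichment is the unweighted mean of per-timepoint estimates,
restricted to timepoints whose deltas exceed the run's delta detection
limits — a weak-signal timepoint (e.g. t = 0) yields an arbitrarily noisy
x and would otherwise dominate the mean. Per-timepoint `d` values keep
their raw (possibly slightly negative) values so the regression stays
unbiased; estimates above 1 are clipped (tolerance 0.5 before the closure
is declared inconsistent — a true d near 1 overshoots at noise level).

Slopes are ordinary least squares with intercept; r² is the squared
Pearson correlation, defined as 0 for a zero-variance response. QC
follows a fixed precedence: below-detection first (final-timepoint Δ³⁰R
against DL(³⁰R) for the N₂ path; closure concentration rise against the
concentration DL for N₂O), then the linearity discard at r² < 0.80
(boundary inclusive: "discard if < 0.80"). Judging detection before
linearity keeps the statistics of the one-sided 95% DL construction
intact: a zero-flux closure is "below detection" about 95% of the time
and a false positive about 5% — not "non-linear". Every closure ends in
exactly one of accepted / discarded / below-detection; nothing is
silently dropped.

Flux conversion assumes ideal gas and a well-mixed headspace:
F = slope · PV/(RT) · 28.014 g N per mol of gas (two N atoms in both N₂
and N₂O) · 10⁴/A · 1440. The headspace is basal area × 0.15 m chamber
height (37.5 L for the 0.50 × 0.50 m chamber); the 0.10 m base insertion
sits below grade and is excluded. Default T = 298.15 K and
P = 101 325 Pa apply when chamber sensors are absent; both are
per-chamber overridable. N₂ flux is the difference of the N₂+N₂O path
flux and the N₂O flux; non-positive differences are flagged below
detection rather than reported as resolved negative emissions.

## Detection limits

DL = t(n−1, one-sided 0.95) × SD, with SD the between-batch standard
deviation of reference analyses (n−1 denominator). One-sided quantiles
reproduce the reported ratio DLs (two-sided would not). MDLs propagate a
DL to flux units over one closure: for N₂, d_min = DL(³⁰R)/aD² times the
0.78084 atmospheric N₂ mol fraction (the simple trace-signal form —
background correction would shift the result by well under 1%); for N₂O
the concentration DL directly. The conventional N₂O concentration DL is
quoted rounded to 0.02 ppm; the `mdl` command reports the MDL from both
the rounded (0.25 g N ha⁻¹ day⁻¹) and unrounded (0.29) chains.

## Campaign aggregation

Daily chamber flux = mean of accepted closures that day; a day whose
closures are all below detection contributes 0 (no resolvable emission);
a day with only discarded closures is linearly interpolated from
neighbouring days and flagged (`gap_filled`) — the gap policy is this
package's choice. Cumulative losses use a midpoint-trapezoid rule with
half-gap constant extension at the ends, so evenly spaced daily values
integrate to their sum. Treatment summaries are mean ± SE over chamber
replicates (n = 4 in the reference design); inferential statistics
(ANOVA etc.) are deliberately out of scope. The product ratio
N₂/(N₂+N₂O_d) is reported both as ratio-of-means and mean-of-ratios,
since field reports are ambiguous between the two. The fertilizer-derived
fraction is aD divided by the fertilizer enrichment, capped at 1 with a
warning; `mass_balance_enrichment` gives the expected pool enrichment
from fertilizer amount/enrichment and the pre-existing soil mineral N.

## Simulator

The simulator runs the measurement model forward: linear headspace
accumulation (no Hutchinson–Mosier-style saturation — consistent with
the observed linearity the r² rule tests for), binomial pairing, mixing,
and Gaussian noise added **in ratio space**, matching how instrument
precision is reported (defaults: ²⁹R 2.85·10⁻⁷, ³⁰R 8.55·10⁻⁷, ⁴⁵R
3.79·10⁻⁴, ⁴⁶R 9.08·10⁻⁵, N₂O concentration 0.013 ppm), plus
concentration noise on the N₂O path. N₂-path currents are emitted with
the major beam normalized to 1; N₂O-path currents are scaled so the
44–46 sum encodes the (noisy) concentration. Reference injections
(ambient air; 1 ppm standard at natural abundance) are interleaved per
closure slot. Everything is deterministic given the seed.

The default configuration encodes the reference campaign: 8 chambers in
two fertilizer treatments (4 replicates each), 7 days, 2 closures per
chamber-day (the real instrument multiplexes 8 chambers sequentially;
the exact interleaving is not modelled — all chambers share each closure
slot), ambient N₂O 0.332 ppm, fertilizer at 0.60 atom fraction. Daily
true flux profiles follow the observed pattern (fertilization/irrigation
pulse, day-3 minimum, day-5 re-irrigation peak) and integrate to the
observed cumulative totals; true aD is 0.46/0.48 and the
denitrification-derived share of N₂O 0.78/0.91 for the low/high rate.

What the simulator does **not** emulate: soil biogeochemical dynamics
(WFPS-driven denitrification, diurnal temperature effects), chamber
leakage, subsoil flux and pore-space storage, NO interference on the
reduced N₂ path, and drift/covariance structure in instrument noise
(noise is i.i.d. Gaussian per injection). Passing recovery tests
therefore demonstrates correctness of the estimator chain under the
method's own assumptions, not robustness to these field effects.

## Test problem sizes and tolerances

The suite verifies: noiseless round-trip identity to 10⁻⁹ relative;
closed-form vs numerical inversion within 1% on an 10×8 (a, d) grid;
enrichment bias < 0.01 absolute over 100 noisy replicates at a = 0.5,
d = 10⁻⁴; median flux recovery error < 10% over 50 seeded single-chamber
campaigns at full noise; and the DL construction's operating points
(~5% exceedances at zero flux, ~50% at flux = MDL) on 1000 simulated
closures each, within generous binomial bands. These sizes keep the full
suite around ten seconds while leaving Monte-Carlo error well inside the
asserted tolerances. All stochastic tests are seeded; hypothesis runs
derandomized.

## Known limitations

* Single-pool binomial pairing only; no Rayleigh fractionation, no
  isotopomer site preference, no two-pool partitioning.
* The N₂+N₂O path difference uses total N₂O flux, so N₂ is understated
  by (1 − pool fraction) × N₂O flux when part of the N₂O is not
  pool-derived — a sub-percent effect at the reference conditions but
  inherent to the difference construction.
* The concentration calibration assumes the standard is at natural
  abundance and detector response is mass-independent across 44–46.
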