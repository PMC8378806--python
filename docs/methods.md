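# Methods

`beefcorridor` models whether beef — principally edible offals, the dominant
imported beef category in Ghana — exported from Burkina Faso can compete in
Ghanaian markets with third-country (mostly European) frozen imports, and
what a shift from live-animal to meat exports would mean for Burkina Faso's
economy. It combines four pieces: a cohort herd model, a monthly market
simulation of the live-animal trade corridor, deterministic landed-cost
accounting, and social-accounting-matrix (SAM) multiplier analysis. This
note records the model structure, the parameter choices made where data are
silent, and the limits of what the synthetic inputs can show.

## Herd demography

Each national herd is six stocks — {female, male} × {juvenile, sub-adult,
adult} — advanced monthly. Flows are births (parturition rate per adult
female, split equally between sexes), deaths (per-cohort mortality),
maturation (juvenile→sub-adult→adult, mean residence 12 and 24 months), and
offtake for sale. Stocks are continuous: the model integrates rates, not
individuals, which keeps the accounting identity

    Δtotal = births − deaths − offtake

exact to floating-point precision and avoids stochastic rounding. All
annual rates are converted with `monthly = 1 − (1 − annual)^(1/12)`.
Outflow probabilities are applied to beginning-of-month stocks; should
their sum exceed one for a cohort they are rescaled proportionally
(competing risks) — never triggered at realistic parameters.

Offtake is price-endogenous through a double-log supply form,
`rate = r0 · s_m · (P/P0)^ε`, clamped to [0, 1]. The cohort elasticities
are fixed at 0.05 (juvenile males and sub-adult females), 0.10 (sub-adult
and adult males), 0 (juvenile females, never sold) and −0.05 (adult
females: breeding stock is withheld when prices rise). `s_m` is a
twelve-month multiplier profile, positive and normalised to mean one so
that seasonality redistributes offtake within the year without changing
its annual level; the default is a smooth ±25% cosine profile peaking in
the December trading season, entirely user-overridable since the published
seasonality is only known qualitatively.

Numeric demographic rates for the two countries are not published, so the
default parameter set (parturition 0.62/yr per adult female; annual
mortality 14% juvenile, 6% sub-adult, 5% adult; base offtake rising with
age for males, zero for juvenile females) is calibrated by
`synth.calibrate_herd`: a single scale factor on the base offtake rates is
root-found (Brent) so the simulated 108-month trajectory reproduces a
target compound growth rate — 1.9%/yr by default, the rate implied by the
observed national stock trend of 7.6 M head (2005) to just over 9 M
(2014). Calibration touches only base rates; elasticities and seasonality
are preserved. Because the target is an endpoint CAGR, it averages the
transient of the (arbitrary) initial cohort structure into the answer;
calibrating over a long horizon (600 months) recovers the asymptotic rate
when true stationarity is needed.

## Live-animal market

A single corridor market carries one live-animal price (CFA per 300-kg
traded animal, anchored at 300,000 CFA at month 0). Supply is the two
herds' marketed offtake. Demand is the sum of the two slaughter sectors'
optimal animal demand (below) and a rest-of-region sink — a Côte d'Ivoire
proxy with constant-elasticity demand (price elasticity −1, unit income
elasticity) calibrated to absorb the residual of month-0 supply after
domestic slaughter (43.7% of supply) and the Ghana trade flow (13.5%),
shares derived from observed trade and slaughter statistics. Bilateral
trade itself is the short side of excess supply and excess demand.

Traders hold inventory with a desired coverage of one month of demand
(trailing three-month mean). The price updates multiplicatively with the
inventory gap, `P_t = P_{t−1}(I*/I)^0.25`, and with the current
demand/supply flow ratio raised to 0.5. The flow term matters: the
inventory-gap rule alone stacks two integrators (inventory accumulates the
flow imbalance; the price accumulates the inventory gap) with no damping,
and the coupled herd–market system then exhibits an explosive multi-year
cattle cycle. Because the flow imbalance is the inventory's derivative,
responding to it is derivative feedback and renders the loop stable while
leaving the fixed point unchanged. Inventory is floored at 5% of desired
to keep the power form defined during extreme transients.

## Slaughter and joint-product pricing

Formal slaughter in each country is modelled as a monopoly — the main
slaughterhouses handle a majority of formal throughput and anchor prices
for informal actors — producing three joint products in fixed per-head
proportions from a carcass specification (live weight × 55% carcass yield,
split 50/50 into high- and low-value cuts, plus offals at 10.4% of live
weight). Burkinabe slaughter animals weigh 240 kg at baseline (300 kg under
the productivity scenario); corridor-traded and Ghanaian animals 300 kg.

With linear inverse demands the optimum solves
`Σ_j max(MR_j(Q), 0) = MC(Q)` segment by segment on the piecewise-linear
aggregate marginal-revenue curve (closed form); any product whose marginal
revenue is negative at the optimum is sold only to the revenue-maximising
quantity and the rest discarded (free disposal). Constant-elasticity
demands fall back to a bracketed numeric profit search with an adaptive
upper bound and a grid fallback (with a warning) if the profit appears
non-concave.

Demand curves are calibrated so the month-0 optimum reproduces the
observed price anchors — Burkina Faso: high 2,000, low 1,200, offal 1,000
CFA/kg; Ghana: high 2,500, low 1,500, offal 1,416 CFA/kg-equivalent,
converted to Cedi at the month-0 cross rate — at quantities consistent
with each country's herd offtake. Slopes come from assumed point
elasticities of demand (−3 high, −2.5 low, −2 offal; |ε| > 1 is required
for a monopoly optimum). The low-value anchor and the Ghanaian cut anchors
are not published and were set once at plausible values between the offal
and high-value prices.

Marginal cost is carried as an index because no slaughter-margin data
exist: `MC_t = MC_0 · (α · live_index · weight_ratio + (1−α) ·
proc_multiplier)`, with `MC_0` the calibration-implied marginal revenue
sum, α = 0.8 the animal-cost share, `live_index` the corridor live price
relative to its anchor (converted to Cedi for Ghana), `weight_ratio` the
scenario slaughter weight relative to 240 kg, and `proc_multiplier` the
processing-cost scenario dial. Anchoring the animal cost at the corridor
per-kg price directly is infeasible: the calibrated marginal revenue at
the observed meat prices is below the liveweight value of the animal,
which is exactly the thin-margin problem the analysis is about.

### Income and exchange-rate transmission

Incomes grow 5%/yr in all three markets (not published; flagged,
configurable). Income shifts each linear demand both vertically
(willingness to pay, exponent 0.3) and horizontally (quantity at a given
price, exponent 0.3); at the calibration point this implies an income
elasticity of quantity demanded between 1.0 and 1.5 depending on the
product, consistent with meat demand in urbanising West Africa. A purely
horizontal shift would cap domestic prices at the fixed demand intercepts
while world prices compound — an artefact, not a finding. Ghanaian demand
is additionally rescaled by the CFA/Cedi cross-rate movement (full
pass-through): meat is a tradable, and Cedi depreciation inflates nominal
Cedi willingness to pay; without this, Ghanaian real willingness to pay
would silently erode at 5%/yr.

## Macro paths and competitiveness accounting

The Cedi depreciates 5%/yr against both the USD and the CFA (the cross
rate is the primitive and CFA/USD is derived, so the currency triangle
holds identically; the fixed-cross scenario sets the CFA/Cedi depreciation
to zero while the USD leg continues). The world offal price grows 2%/yr
from 1.11 USD/kg. CFA/USD is 574.7 (the rate implied by the 1,000 CFA/kg =
1.74 USD/kg equivalence); the CFA/EUR peg is 655.957.

The import cost ladder accumulates FOB → +freight (3,500 EUR per 25-t
container at 1.18 USD/EUR = 0.165 USD/kg) → CIF → +35% tariff → +5–8%
trader margin, unrounded, and reports 2-decimal display lines alongside;
the printed wholesale prices (1.86 / 1.81 USD/kg) are reproduced only by
unrounded accumulation — summing the rounded lines gives 1.87. Burkinabe
exports land at ex-abattoir + 10% ad-valorem transport + 1% informal
charges on the subtotal (1,000 → 1,111 CFA/kg). Refrigerated transport is
0.13 USD/ton/km with a 52% West-Africa uplift (4,940 USD per 25-t,
1,000-km load). Trade records are classified by unit value: offal HS 0206
rows always `offal`; fresh/frozen rows below 1.53 USD/kg `byproduct`. The
threshold is 1.53 rather than the narrated 1.50 because the printed
low-value totals include a row with unit value 1.52; rows within ±0.05 of
the threshold are reported so the sensitivity of the cut-off is visible.

## Scenarios

Seven deterministic 120-month runs, reported from month 36 after herd
burn-in (month-36 stocks sit within 2% of the reporting-window trend):

- **baseline** — anchors as above;
- **segmentation** — 20% of high-value cuts divert to a premium segmented
  market at 4,000 CFA/kg (vs the 2,000 domestic anchor). The segment is
  perfectly elastic, so its revenue is linear in the composite quantity
  and enters the monopoly problem as an offset against marginal cost while
  the domestic high-value curve faces only the remaining output; the
  segment price grows with the same income transmission as domestic
  willingness to pay. A one-for-one shift of the whole domestic demand
  curve to the 4,000 level would instead expand slaughter by ~75% and
  collapse the offal price — far from the "slight" responses the thin
  premium market for Sahelian beef supports;
- **productivity** — Burkinabe slaughter weight 240 → 300 kg;
- **cost** — processing-cost multiplier 0.8 (a 20% cut to the (1−α) share);
- **combined** — all three;
- **no-depreciation** — fixed CFA/Cedi cross (Eco-currency reading);
- **north** — Burkinabe offals haul 150 km at the refrigerated rate
  instead of the ad-valorem coastal ladder, and third-country imports bear
  800 km of inland haulage; both distances are configuration defaults, not
  observed values.

The qualitative outcome surface: the baseline gap between Burkinabe landed
offals and third-country wholesale (in Cedi/kg) is positive in every
reported month and widens; segmentation raises the Ghanaian domestic offal
price and slightly lowers the Burkinabe price; the processing-cost cut
lowers the Burkinabe price and very slightly raises the Ghanaian one
(both routes work through the live-animal market: more slaughter demand in
Burkina Faso tightens animal supply for trade); the combined strategy
narrows the gap without closing it on the reporting-window and final-year
means — at the very end of the horizon the seasonal supply peak briefly
grazes parity, a genuine model finding; the fixed-cross regime narrows the
gap far more than any supply-side strategy. Burkinabe landed offals
undercut Ghanaian fresh offals in every year on annual means, though
late-horizon seasonal peaks can touch the Ghanaian price.

## SAM multipliers and employment

The SAM is a balanced square ledger (units: million CFA) with activities,
commodities, factors and households endogenous. Coefficients divide each
endogenous cell by its full column total (so leakage to exogenous accounts
keeps column sums below one and the spectral radius below one); the
multiplier matrix is `(I − A)^−1`, checked against its defining identity
at 1e−8. Export-demand shocks land on commodity rows; gross production
aggregates activity-row impacts (commodity impacts are reported separately
to avoid double counting), GDP the factor rows (value-added definition —
the aggregation is a package choice), household income the household rows.
Employment uses the wage-bill method: aggregate employment is allocated to
accounts in proportion to wage bills (jobs are invariant to rescaling all
wages), giving employment–output ratios applied to activity impacts.

The real 2013 Burkina Faso SAM is not redistributable, so
`synth.generate_sam` builds a balanced synthetic stand-in: endogenous
expenditure shares are drawn from concentrated Dirichlet distributions
encoding the essential structure — the meat activity buys the cattle
commodity heavily (a long upstream chain) while the cattle activity is
mostly value added — endogenous totals are closed through the Leontief
inverse against drawn exogenous injections, and exogenous accounts are
balanced by clearing transfers through the government account. Balance is
exact by construction; RAS scaling is provided separately for
user-supplied unbalanced SAMs. The packaged shock scenario (live cattle
19,170 MCFA; meat-equivalent 23,090 MCFA) reproduces the qualitative
ordering — the meat shock generates more gross production — and its
percentages are synthetic-scale, not national-scale.

## What the synthetic inputs do and do not show

Synthetic SAMs preserve balance, leakage and the cattle/meat chain
asymmetry but none of the 2013 Burkinabe account magnitudes, so absolute
CFA and job impacts are not comparable with national results — only
orderings and structural properties are tested. Synthetic trade tables
reproduce the unit-value mixture of the observed import basket, not its
country composition. The corridor model's supplementary calibration
constants (demand intercepts, inventory sensitivities, seasonal values)
are package choices anchored to the published point values; trajectories
are therefore meaningful as qualitative signs and orderings, not as
forecasts. Problem sizes throughout (120-month horizons, ≤20-account SAMs,
108-month calibrations) were chosen as the smallest that exercise the full
mechanism cleanly.

## Known limitations

No purchase inflows into herds; no feed or rangeland feedback; exchange
rates and world prices are exogenous; meat storage is not dynamic; the
import-demand curve does not feed back into the Ghanaian domestic offal
market (imperfect substitutes, one-way coupling); oligopoly and strategic
interaction are out of scope; Nigeria is proxied out of the rest-of-region
sink.
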