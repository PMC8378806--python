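# beefcorridor

Can Burkina Faso out-compete third-country suppliers by exporting beef —
principally edible offals, the dominant imported beef product in Ghana —
instead of live cattle? `beefcorridor` is a desk-scale toolkit for that
question, aimed at agricultural economists and livestock value-chain
analysts working on Sahel–coastal West Africa trade. It provides:

- a **cohort herd model**: monthly sex × age stocks with price-endogenous,
  seasonal offtake, `rate = r0 · s_m · (P/P0)^ε`, with negative ε for
  breeding females;
- a **corridor market simulation**: a Sterman-style inventory price rule
  `P_t = P_{t−1}(I*/I)^s` for live animals, bilateral trade as the short
  side of excess supply and demand, a rest-of-region demand sink, and an
  offal import-demand curve in the world price, the domestic price and
  income;
- **joint-product monopoly pricing**: carcasses yield high-value cuts,
  low-value cuts and offals in fixed proportions, and the slaughterhouse
  produces where `Σ_j max(MR_j(Q), 0) = MC(Q)`, discarding any product
  whose marginal revenue turns negative (free disposal);
- **landed-cost accounting**: FOB → CIF → tariff → margin ladders for
  imports, ad-valorem transport plus informal charges for corridor
  exports, refrigerated transport costing, and unit-value classification
  of trade records into offals, low-value by-products and high-value cuts;
- **SAM multiplier analysis**: balanced social accounting matrices, the
  Leontief inverse `(I − A)^−1` over endogenous accounts, export-demand
  shocks, and wage-bill-based employment impacts;
- a **scenario engine** running seven deterministic 120-month scenarios
  (baseline, market segmentation, animal productivity, processing costs,
  their combination, a fixed CFA/Cedi cross, and a Northern-Ghana
  destination market);
- a **synthetic-data module** generating balanced SAMs and trade tables
  from a seed, plus the packaged reference tables the calculations anchor
  to.

See `docs/methods.md` for the model assumptions and parameter choices.

## Worked example

The import cost ladder and the Burkinabe landed price, the core of the
baseline competitiveness comparison:

```python
>>> from beefcorridor.competitiveness import (
...     CostLadder, TransportSpec, import_wholesale_price, landed_export_price)
>>> import_wholesale_price(CostLadder(margin_rate=0.08)).lines_rounded
{'fob': 1.11, 'freight': 0.17, 'cif': 1.28, 'tariff': 0.45, 'margin': 0.14,
 'wholesale': 1.86}
>>> landed_export_price(1000.0, TransportSpec())
LandedPrice(ex_abattoir=1000.0, transport=100.0, informal=11.0, landed=1111.0)
```

Imported offals wholesale at 1.86 USD/kg (about 1,069 CFA/kg) with the
high 8% trader margin, 1.81 USD/kg with the low 5% margin. Fresh Burkinabe
offals land in Ghana at 1,111 CFA/kg — cheaper than domestically produced
fresh offals (1,416 CFA/kg) but above the imported wholesale range, which
is the crux of the competitiveness problem.

The simulation extends this comparison over ten years (prices in Cedi/kg;
reporting starts after the 36-month herd burn-in):

```python
>>> from beefcorridor.scenarios import run_scenario
>>> df = run_scenario("baseline")
>>> cols = ["month", "bf_landed_cedi", "world_wholesale_cedi",
...         "gh_offal_cedi", "gap_world_cedi"]
>>> df[cols].iloc[[36, 72, 119]].round(2)
```

```text
 month  bf_landed_cedi  world_wholesale_cedi  gh_offal_cedi  gap_world_cedi
    36           12.44                 10.41          14.77            2.04
    72           15.31                 12.69          16.99            2.61
   119           19.71                 16.46          20.21            3.25
```

Burkinabe offals stay below the Ghanaian fresh-offal price but above
third-country imports throughout, and the gap to world suppliers widens —
Cedi depreciation against the CFA raises the Cedi cost of Burkinabe
products faster than world prices grow. The `sign_table` helper summarises
all scenarios; the only intervention that substantially narrows the gap is
the macroeconomic one (a fixed CFA/Cedi cross).

A command-line interface wraps the main workflows:

```sh
beefcorridor competitiveness            # cost ladders + trade classification
beefcorridor simulate --scenario all    # all scenarios, tidy CSV + sign table
beefcorridor sam --sam-file sam.csv --classes-file classes.csv \
    --shock-account com_meat --shock-value 23090
beefcorridor synth --seed 1             # synthetic SAM and trade table
```

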