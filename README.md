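# needspend

Need-weighted capitation and cost-per-weighted-patient comparison of
practice-level acute hospital spending.

## The problem

Commissioners in the English NHS buy acute hospital care for the
populations registered with general practices. Comparing raw spending
between practices is meaningless — populations differ in age, sex,
deprivation and local cost conditions — so allocation-style *need
weighting* is used to standardize: each registered person is multiplied by
need coefficients so that a population expected to cost twice as much
counts as twice as many *weighted patients*. Total spend divided by
weighted patients then gives a comparable **cost per weighted patient**
(cost pwp).

`needspend` implements this chain end to end for the question "does a
large, atypical (for example digital-first, working-age-heavy) practice
spend less on acute care than its region, after need adjustment?" It is
aimed at health-economics and commissioning analysts working with
practice-level FOI-style extracts: total spend per practice per financial
year, plus quarterly registered populations by age-sex band.

## The method

For practice *p* with averaged quarterly band counts *n₍pb₎*, weighted
population under the core-services style scheme is

```
W_p = [ Σ_b n_pb · ( Σ_c λ_c · w_cb ) ] · Π_f F_pf
```

with per-service need components *c* (general & acute, mental health,
maternity, community, prescribing), component weights λ summing to 1, and
multiplicative local factors *F* (utilization, supply, price, unmet need,
deprivation, smallness) for the practice's area. Three schemes are
provided:

* **core services** — full component set, home-area local factors;
* **core services adapted** — only the general & acute and maternity
  components (matching spend data that exclude mental-health, community
  and prescribing costs), evaluated on the practice's *actual* averaged
  profile, with local factors averaged over the areas patients actually
  live in;
* **Carr-Hill** — a primary-care workload curve times mortality, market
  forces and rurality factors, with a nursing-home premium.

The engines are strictly coefficient-table driven; no official NHS
coefficients are bundled (the `synthetic` module generates clearly
labelled synthetic tables with a U-shaped age-cost curve and a deprivation
gradient).

Bespoke focal-practice corrections are applied in a fixed, ledgered order:
out-of-region site cohort removal (population only) → reference-priced
cohort removal (spend, registered and weighted) → cost pwp → expected-cost
correction (the cost pwp is inflated by the relative shortfall of
modified vs baseline expected costs, computable from attendance rates,
unit costs and prior-use modifiers, or pinned, e.g. at 0.12) → GDP-deflator
restatement of earlier years.

The focal entity is compared against the regional primary-care networks
(~50,000 patients each) with a one-sided simple *z* test,
`z = (x_focal − mean) / sd(n−1)`, `p = Φ(z)`, reported only where the
network distribution passes a Shapiro-Wilk + Kolmogorov-Smirnov normality
screen; at practice level a percentile rank (1st = lowest cost pwp) is
reported instead. Savings roll up as `W_focal × (reference − focal)`.

## Worked example

```python
from needspend.synthetic import RegionConfig, generate_region
from needspend.pipeline import analyse_region
from needspend.reporting import comparison_table

region = generate_region(RegionConfig.desk_scale(seed=11))   # 60 practices, 8 networks
bundle = analyse_region(
    region.population, region.spend, region.analysis_tables,
    focal_practice_id="FOCAL", financial_years=["2019/20"],
    resident_mix=region.resident_mix,
    nursing_home_rates=region.nursing_home_rates,
)
print(comparison_table(bundle).to_string(index=False))
```

prints

```
               scheme financial_year focal_cost_pwp reference_cost_pwp difference difference_pct         p_one_sided  percentile total_savings
        core_services        2019/20           £515               £724      £-209         -28.9% n/a (screen failed)           5        £6.72M
core_services_adapted        2019/20           £614               £758      £-144         -19.0%            1.71e-05          10        £3.89M
            carr_hill        2019/20           £396               £729      £-332         -45.6%            4.73e-05           2        £13.9M
```

The synthetic focal practice was generated with a true spend multiplier of
0.65, so its cost per weighted patient sits well below the regional
reference under every scheme (the exact figure varies with scheme and
seed: this small region's spend noise is deliberately realistic). Where
the 8-network reference sample fails the normality screen, no *z* result
is reported — only the percentile rank among the 61 practices.

The same flow is available from the shell:

```
needspend simulate --seed 11 --out region/
needspend run --config run.yaml
needspend reproduce
```

`needspend reproduce` re-derives a published study's printed worked
arithmetic (population subtraction, cohort spend flow, band shares,
cost-difference rows, savings) from its printed inputs and confirms every
figure matches.

## Layout

| module | contents |
| --- | --- |
| `needspend.population` | age-sex bands, quarterly snapshots, averaged registered population, CSV interfaces |
| `needspend.weighting` | coefficient tables (YAML), the three weighting engines, need index |
| `needspend.adjustments` | cohort removals, expected-cost correction, GDP-deflator inflation, audit ledger |
| `needspend.comparison` | cost pwp, network aggregation, normality screen, one-sided z, percentile, savings |
| `needspend.synthetic` | seeded region and coefficient generators with ground-truth manifest |
| `needspend.pipeline` / `reporting` / `cli` | orchestration, report tables, command line |
| `needspend.worked_example` | the published-arithmetic regression |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
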