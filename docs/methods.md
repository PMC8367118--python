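# Methods

This note records the modelling choices behind `needspend`: what each
stage assumes, which defaults matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Populations and averaging

A practice-year is represented by 1–4 quarterly snapshots of age-sex band
counts (financial year April 1 – March 31; quarters anchored at April,
July, October, January; snapshots outside the year are rejected). The
working population for all downstream stages is the band-wise arithmetic
mean over the available snapshots. Practices observed for fewer than four
quarters are averaged over what exists — no imputation — and fractional
persons are carried at full precision until report formatting. The
canonical banding is 0–19 / 20–39 / 40–59 / 60–79 / 80+ per sex, but any
disjoint banding covering age 0 to open-ended is accepted.

## Weighting schemes

All three engines are homogeneous of degree 1 in the population and purely
table-driven. Composition is fixed as

    weighted = (band-level product-sum) × (product of local factors),

a choice the package declares rather than inherits: capitation formulas
are conventionally multiplicative in their adjustment factors, but nothing
in the inputs forces it, so the multiplicative convention is documented
here and enforced uniformly.

Scheme specifics:

* **core services** — combined band need is the component-weight average of
  per-service multipliers; the component weights must sum to 1. Local
  factors are those of the practice's home area. The *smallness* factor is
  an ordinary table entry; tables generated here set it to 1, which is also
  the sensible value for any practice large enough that unavoidable-
  smallness costs cannot apply (the focal practices this package targets
  are tens of thousands of patients).
* **core services adapted** — component set restricted to general & acute
  and maternity, reweighted to sum to 1 (enforced by the table schema);
  always evaluated on the actual averaged profile; the local factor is the
  residence-mix-weighted mean of per-area factor *products*. With a
  single-area mix and the same need curves it reproduces the core engine
  exactly (tested).
* **Carr-Hill** — age-sex workload curve × mortality × market forces ×
  rurality × (1 + premium × nursing-home rate). Rurality has been phased
  out of practice and defaults to a neutral 1 in generated tables; the
  premium is a table-level scalar (0.43 in generated tables). Unmet need
  enters only as the mortality multiplier the table supplies; no standard
  mortality ratio is computed internally.

### Coefficient tables and normalization

A table carries its banding, multipliers, per-area factors, a
`reference_shares` mixture and a `reference_mean`. Validation checks that
the reference mixture, evaluated with neutral local factors, yields exactly
`reference_mean`. The interpretation adopted is population-weighted: the
reference mean is the need index of the reference (regional/national)
population mixture, so the realized population-weighted mean practice need
index in a region drawn from that mixture matches `reference_mean` up to
sampling error (tested at 5% tolerance on the desk-scale region). A
uniform-over-bands population would give a different (larger) index
because elderly bands are rare but expensive; the population-weighted
reading is the one under which "the average practice has index ≈ 0.93"
makes sense.

## Adjustments

The adjustment order is fixed for reproducibility: site-cohort removal →
reference-cohort removal → weighting → cost per weighted patient →
expected-cost correction applied to the *ratio* → inflation restatement
for non-target years. Site removal touches only the population (the spend
extract never contained the remote site's hospital costs). The reference
cohort is removed at externally supplied averages: spend −= size × cost
per patient, weighted −= size × need index; removing a cohort at the
practice's own averages provably leaves cost pwp unchanged
(mean-preserving deletion, tested).

The expected-cost correction factor is

    (expected_base − expected_modified) / expected_base,

where expected costs are Σ band count × attendance rate × unit cost over
service categories (default categories: ED, outpatient, inpatient;
configurable via the modifier table), and the modified sum multiplies each
rate by a prior-use modifier. The factor is recomputed per financial year
from that year's profile by default; a pinned mode (e.g. 0.12) reproduces
a fixed published factor when the underlying rate tables are unavailable.
The factor is invariant to uniform scaling of unit costs and of the
population (tested).

Inflation uses a two-column financial-year → index series (a whole-economy
GDP deflator in practice; not bundled): cost × index_target / index_source.
Restatement composes exactly across years (tested to 1e-12).

Every step appends to an `AdjustmentLedger`; replaying the ledger from the
raw totals must reproduce each recorded intermediate exactly, which guards
against silent drift between the audit trail and the computation.

## Statistical comparison

The focal entity enters as a single observation against the distribution
of reference network cost pwp values (ratio of summed spend to summed
weighted within each network — never the mean of member ratios). The
focal practice's own network is excluded from the reference sample, as is
the focal practice from the reference cost pwp. The z statistic uses the
sample standard deviation with the n−1 denominator by default; a `ddof=0`
switch gives the n denominator, since "simple z test" does not pin this
down. p is the standard-normal lower tail (alternative: focal lower).

The z result is only reported at aggregation levels whose reference sample
passes both a Shapiro-Wilk and a Kolmogorov-Smirnov test at α (default
0.05). The KS variant used is the common applied one — against a normal
with the sample's own mean and standard deviation. A zero-variance
reference sample (possible in noise-free synthetic limits) reports no z
rather than erroring the pipeline. At practice level, where spend
distributions are heavy-tailed, a percentile rank is reported instead:
ceil(100 · #{values ≤ focal} / (n+1)) clamped to [1, 100], ties counted as
≤, 1st percentile = lowest spending.

Per-weighted-patient savings net of extra primary-care provision are
`difference − round(extra_appointment_fraction × funding_per_patient)`.

## Synthetic regions

The generator emulates an FOI-style regional extract with known ground
truth. Defaults describe a large urban English commissioning region:

| parameter | default | rationale |
| --- | --- | --- |
| practices / networks | 357 / 48 (+1 focal each) | regional scale, ~50k patients per network |
| mean list size | 6,900 (lognormal, σ=0.45) | regional practice-size distribution, right-skewed |
| age-sex mixture | working-age-heavy urban shares | drawn per practice from a Dirichlet (conc. 300) around the regional mixture |
| base cost per need unit | £715/year | acute cost pwp magnitude for such regions |
| spend noise | gamma, shape 50 × weighted/reference-weighted | see below |
| focal quarterly sizes | 55k → 67k | a large practice growing within the year |
| focal 20–39 share | 0.855 | a digital-first, working-age membership |
| focal spend multiplier | 0.65 | the effect size the pipeline should recover |

Spend noise is multiplicative gamma with mean 1 and shape proportional to
the practice's weighted population. Two reasons: (i) spends stay positive
and right-skewed at practice level, with relative dispersion shrinking as
1/√size, as patient-level cost variation aggregates; (ii) practice spends
become sums of iid gamma increments on a common scale, so any aggregate —
a network, or one very large practice — of equal weighted size has the
*same* cost pwp distribution. That is precisely the condition under which
comparing a single large focal entity to the network distribution is
calibrated, and it is why the type-I-error experiment sizes the focal
practice to match the expected network weighted total. Network-level
aggregates are then near-normal and usually pass the screen, while
practice-level values are skewed — the generator reproduces that contrast.

The generating truth prices every practice, including the focal one, at
its home area's factor product under the core-services generating table;
the focal residence mix is emitted for the adapted scheme to consume. By
default the analysis uses the generating tables (well-specified case); a
perturbation mode swaps in jittered tables to study robustness.

Generated coefficient tables follow a U-shaped age-cost curve (trough in
young adulthood, steep rise after 60), a maternity bump for women 15–45,
working-age-concentrated mental-health need, an acute component that
weights healthy young adults low, and a deprivation-increasing local
factor; per-area factor products are normalized to mean 1 so the regional
need index lands on the normalization target (0.93 by default). The
resulting scheme ordering for a young-skewed practice — adapted index <
core index < Carr-Hill index — matches what those formulas' structures
imply.

What the generator does **not** emulate: disease mix, seasonality,
patient-level events, list churn within quarters, correlated shocks
across practices (e.g. a hospital closing), or coefficient drift over
time. Passing recovery tests therefore demonstrates that the pipeline's
arithmetic and statistics recover a known multiplicative spend effect
under realistic dispersion — not that the weighting schemes remove
confounding in real data.

### Experiment scales

The recovery experiment uses 20 desk-scale regions (60 practices, 8
networks, ~465k people each; seconds per region); the per-seed estimate
has a standard deviation near 4–5 percentage points, so the 20-seed mean
identifies the −35% truth to about ±2. Under zero spend noise the recovery
is exact. The type-I experiment uses 200 reduced regions (96 practices, 48
networks of mean list 3,000) so that the reference sample is large enough
(48 networks) for the z test's normal approximation to be honest; with
only 8 reference networks the n−1-denominator z over-rejects by design,
which is a property of the test, not of the implementation. Replicates
whose reference sample fails the normality screen report no z and count as
non-rejections, mirroring the pipeline's reporting rule.

## Numerical conventions

Half-up rounding; per-patient costs formatted as whole pounds, totals to 3
significant figures in millions, percentages to 1 decimal (2 in the
population-shares table); full-precision values are always written
alongside formatted tables. Monetary units are GBP throughout. Degenerate
inputs (zero totals, zero variance, missing areas/bands/years) raise typed
errors naming the offending path rather than defaulting silently.

## Known limitations

* Official allocation coefficients are not reproduced; results on real
  data depend entirely on the coefficient tables supplied.
* The expected-cost correction is only as good as the attendance/unit-cost
  /modifier tables; with the pinned mode it is a single scalar.
* The one-sided z treats the focal value as a fixed observation; no
  uncertainty in the focal practice's own cost pwp is propagated.
* Percentile ranks and p-values computed on small reference samples (few
  networks) are coarse; the screen guards normality, not sample size.
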