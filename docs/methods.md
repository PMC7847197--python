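# Methods

## Scope and model

The package implements a reference-condition bioassessment for streams
receiving metal contamination. Its statistical model has three layers:

1. **Exposure** — per-site dissolved Cu, Zn, Cd, Pb are reduced to a single
   toxic-unit score, the cumulative criterion unit
   CCU = Σᵢ mᵢ/cᵢ, where cᵢ is the U.S. EPA freshwater chronic criterion
   (CCC) at the survey's water hardness. The criteria are the 2006 national
   recommended hardness equations, `exp(mA·ln H + bA)·CF(H)`, with the
   dissolved conversion factor CF constant for Cu (0.960) and Zn (0.986)
   and hardness-dependent for Cd (1.101672 − 0.041838·ln H) and Pb
   (1.46203 − 0.145712·ln H). The constants are embedded as code-level
   package data and can be overridden by constructing a `CriterionSet`
   directly.

2. **Response metrics** — stone-level invertebrate counts yield eight
   community metrics (total and order-level abundance/richness for
   Ephemeroptera, Trichoptera, Diptera) plus dominant-family abundances;
   electrofishing areas yield per-species abundance; individual fish yield
   the Fulton-type condition factor 1000·W/L³. Abundances are
   log₁₀(x+1)-transformed per replicate (stone or area) *before* site
   aggregation; richness and condition factor are analysed untransformed.
   Condition factors are pooled across areas within a site (the individual
   fish is the replicate).

3. **Decision rule** — each metric × contaminated site gets two independent
   gates. The *range gate* asks whether the site mean falls outside the 90%
   prediction interval of an intercept-only fit to the reference-site
   means: mean ± t₀.₉₅,ₙ₋₁·s·√(1+1/n). The *test gate* asks whether the
   adjusted p of the site's paired contrast is below 0.05, where contrasts
   come from a homogeneous-variance one-way ANOVA over all sites and the
   adjustment is single-step max-|t|: pᵢ = 1 − P(maxⱼ|Tⱼ| ≤ |tᵢ|) under the
   central multivariate t with the contrasts' correlation matrix and the
   residual degrees of freedom. Labels: both gates → adverse; exactly one →
   some concern; neither → no concern.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| hardness | 10 mg/L CaCO₃ | criteria evaluation point; below the 20 mg/L calibration floor of the criteria a warning is logged (soft boreal streams routinely sit there) |
| censoring policy | `zero` | substitution for below-LOQ values; `half_loq` and `loq` selectable. Zero substitution is the conservative-downward choice and reproduces the reference-site CCUs of the bundled survey table |
| `use_rounded_criteria` | true | score CCUs against criteria rounded to reporting precision (1 d.p. Cu/Zn, 2 d.p. Cd/Pb), the convention of printed survey tables; full precision available |
| α (range gate) | 0.10 | prediction-interval level (90%) |
| α (test gate) | 0.05 | significance level on adjusted p |
| dominant-family share | 0.05 | a family must exceed this share of total abundance on ≥1 stone (`any_stone`; an `all_stones` reading is selectable) |
| dominant-family occupancy | 0.30 | the family must occur on strictly more than ⌈0.30·n_stones⌉ stones — with the 45-stone design, more than 14, i.e. at least 15 |
| rare-species floor | 5 | fish species with ≤5 total captures are excluded from site comparisons |

## Numerical choices

* The joint multivariate-t probability is evaluated with scipy's
  quasi-random integrator, seed fixed at 20180626 and a quadrature budget
  of 25 000 points per dimension (absolute error ≈ 1e-4, far inside the
  2e-3 agreement we verify against a 10⁶-draw Monte-Carlo max-|t|
  simulation). A single contrast is the exact two-sided t p-value (the max
  over one coordinate), so the k = 1 case is closed-form.
* Adjusted p is floored at the raw two-sided p and capped at 1, guarding
  against integration noise violating p_adj ≥ p_raw.
* Zero-variance degenerate fits are flagged, not silently propagated; a
  zero estimate with zero variance yields t = 0, p = 1.
* Replicate water samples are averaged per site and metal after censoring
  substitution; per-replicate CCUs are available through `compute_ccu`.
* CCU reports round to 1 decimal; all internal arithmetic is full
  precision.
* Reference ranges with fewer than two reference means (a species caught at
  a single reference site) are undefined: the range gate is skipped and the
  classification carries a note, so such metrics can at most reach "some
  concern" through the test gate.
* Percent differences between sites are computed on the back-transformed
  abundance scale (10^mean − 1) by default; a `raw_mean` switch compares
  the analysis-scale means directly.

## The bundled survey table

`data/tokushibetsu_water_june2018.csv` holds the printed water-chemistry
measurements of a nine-site survey (five contaminated, four reference) of
the Tokushibetsu River system, Hokkaido, June 2018, with `<LOQ` tokens for
censored cells. Recomputing CCUs from these *rounded* concentrations and
the rounded criteria row reproduces the reported values at S1a (8.4),
S1b (9.4), R1 (2.1), R2 (0.1), R3 (0.3) and R4 (0.3). At S2, S3 and S4 the
recomputation gives 6.9, 3.7 and 0.8 against reported 6.8, 3.8 and 0.9: the
original calculation evidently used unrounded laboratory concentrations,
which the printed table cannot recover. These three sites are therefore
excluded from exact round-trip checks; the discrepancy is ±0.1 CCU.

## The synthetic survey generator

`ScenarioConfig` emulates the paired design: 9 sites (S1a, S1b, S2–S4
contaminated; R1–R4 reference, elevation-matched, S1a/S1b sharing R1),
5 stones and 5 fish areas per site, 3 water replicates. Benthic counts are
negative binomial (size 3 — overdispersion typical of stone samples) with
means declining exponentially in site CCU,
E[count] = mean·exp(−β·s·CCU), where s is a per-taxon sensitivity weight
(heptageniid mayflies 1.0 down to chironomids 0.3). The default β,
ln(10)/9.4, makes a fully sensitive taxon decline 90% at the most
contaminated site; β = 0 gives exchangeable sites (the null). Fish catches
are Poisson per area with lognormal fork lengths and a cubic allometric
weight model W = a·L³·exp(ε) (a = 0.01, so condition factors concentrate
near 10); lengths and weights are recorded at 0.1 cm / 0.1 g resolution, as
measured in the field. Hatchery-origin marks are Bernoulli per fish with
site-specific proportions; otolith subsamples read up to 25 fish per site.
Water replicates carry 5% lognormal measurement noise around the per-site
means, censored below the LOQs (0.001 Cu, 0.06 Zn, 0.005 Cd/Pb µg/L).

The generator reproduces the *statistical* structure the analysis assumes —
overdispersed counts, replicate noise, paired design, censoring — not
ecological realism: no spatial autocorrelation, no inter-taxon dependence,
no seasonal dynamics, and an exponential dose–response chosen for
monotonicity, not mechanism. Tests that pass on synthetic surveys therefore
validate the *procedure* (error rates, power, bookkeeping), not any claim
about real communities.

## Operating characteristics (as computed by the test suite)

The null error rate of the "adverse" label is estimated over 1000 simulated
surveys (β = 0) of the total-abundance metric: the conjunction of the two
gates fires in well under 5% of metric × site classifications and strictly
less often than either gate alone (the range gate alone runs near its
nominal 10%). Power is estimated over 400 surveys with a uniform 90%
reduction at the two most upstream contaminated sites: those sites are
flagged adverse or some-concern in ≥90% of surveys. These simulation sizes
keep Monte-Carlo error a small fraction of the margins being checked; the
operating-characteristic runs use a reduced quadrature budget (2000
points/dimension, joint probabilities to ~1e-3) since label boundaries are
insensitive at that scale.

## Limitations

* The criteria adjust for hardness only; pH, DOC and other modifiers of
  metal bioavailability are ignored (biotic-ligand-model criteria are out
  of scope).
* The pooled-variance ANOVA assumes homogeneous within-site variance on the
  analysis scale; a per-pair Welch option is provided as a sensitivity
  check (its joint adjustment uses the smallest Welch df, conservative).
* Whether richness metrics should be transformed before testing is a
  judgement call; they are analysed raw here, as count-scale means.
* Single-occasion grab samples stand in for long-term exposure; the CCU is
  a screening index, not a dose estimate.
* A field study's published classifications can only be reproduced from its
  raw replicate-level data; the pipeline accepts such data as CSVs but does
  not bundle any.
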