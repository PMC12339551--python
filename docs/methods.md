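# Methods

`necrostoich` packages the quantitative backbone of a straw-amendment field
trial in which the stoichiometry of the added substrate (C:N:P:S) is tuned
from fungal (oligotroph) to bacterial (copiotroph) demand, and the fate of
the added carbon is tracked through amino-sugar and lignin-phenol biomarkers.
This note records the models, the parameters that matter, and the design
choices made where the published procedure left room.

## Stoichiometric amendment design (`stoich_design`)

The design treats humification as pure bookkeeping: a fixed fraction
(default 0.30) of the residue C is assumed to stabilize, and that humified C
is the denominator of every stoichiometric ratio. With residue applied at
`m` g per 100 g dry soil and elemental concentrations in g kg⁻¹, the
product `m × conc` is already in mg per 100 g soil, the unit used for every
per-soil mass in the package.

Ratios are expressed as mass parts per 10,000 parts C. The forward map is

    ratio_E = (base_E + add_E) / humified_C × 10,000,   E ∈ {N, P, S}

and the inverse (`solve_additions`) is its exact algebraic inversion,
floored at zero: an element the residue already over-supplies gets no
addition and is flagged in `AmendmentRecipe.floored`, because nutrients
cannot be removed from soil. Consequently the round-trip invariant is
one-sided: realized ratios are ≥ the target, with equality when nothing
was floored. Full precision is kept internally; integers appear only at the
display boundary (`StoichTarget.rounded`).

Demand presets: fungal 10,000 : 1,034 : 110 : 94 and bacterial
10,000 : 2,004 : 494 : 264 (mass basis). The three published amended
treatments used design targets 1,034/167/133 (NPS1), 1,556/238/171 (NPS2,
a custom intermediate not tied to either preset) and 2,004/494/264 (NPS3);
NPS1's P and S targets exceed the fungal preset, and the package reproduces
the published additions as printed rather than guessing intent. One cell of
the published recipe constants (the NPS2 P addition, 3.57 mg) is stored as
the value consistent with both the treatment's design ratio (238) and the
inverse arithmetic that regenerates every other published addition.

Solution concentrations fall out of the units: mg per 100 g soil divided by
mL per 100 g soil is g L⁻¹, so at the experiment's 1 mL dose the numbers
coincide with the additions. The salt formulation assumes anhydrous
NH₄NO₃ / KH₂PO₄ / (NH₄)₂SO₄ (the source is silent on hydrates): sulfate
carries all S, phosphate all P, and the N that the sulfate brings along is
credited before NH₄NO₃ makes up the remainder. If the sulfate's N alone
exceeds the N request the formulation is infeasible with this salt set and
the surplus is reported. Elemental conservation of the decomposed salts is
a tested invariant (1e-9 relative).

## Necromass accounting (`necromass`)

Bacterial necromass C: `BNC = 45 × MurA` (muramic acid is exclusively
bacterial). Fungal necromass C subtracts the bacterial share of glucosamine
at 2 mol GlcN per mol MurA before applying the fungal coefficient:

    FNC = 9 × (GlcN − 2 × MurA × 179.17/251.23)

with 179.17 and 251.23 the molecular weights of GlcN and MurA. MNC is their
sum. Plant necromass C scales each CuO-oxidation phenol class by its release
fraction (V 0.33, S 0.90, C 1.00), divides the summed lignin by the 8%
minimum lignin content of major crop residues, and converts μg to mg:

    PNC = (V/0.33 + S/0.90 + C/1.00) / (0.08 × 1,000)

All conversion coefficients are frozen literature constants
(`constants.ConversionConstants`); no uncertainty is propagated through
them. C/V and S/V are reported as lignin-transformation diagnostics (lower
= more microbially transformed), and pool/SOC contributions as plain
percentages.

Numerical choices: a sample with MurA large relative to GlcN gives a
negative raw FNC; since a necromass pool cannot be negative and no handling
rule is published, the value is clamped to 0 with a per-record
`fnc_clamped` flag and a `DataQualityWarning`. Negatives within 1e-9 of
zero are treated as roundoff at the exact algebraic boundary and clamped
silently. Group summaries average replicate-level pool values; because all
conversions are linear this equals converting mean biomarkers, which is
asserted as a test rather than assumed.

## Enzyme stoichiometry (`enzyme_stoich`)

The C:N:P acquisition ratios use the standard ecoenzymatic grouping —
C = BG + CBH, N = NAG + LAP, P = AP — since no alternative formula is
published for this assay set. The identity C:P = (C:N) × (N:P) holds
exactly and is property-tested. A `log_transform` option applies
ln(1 + activity) to each pooled channel first, the form used in
ecoenzymatic vector analyses, because which variant the original summary
tables used is not documented.

## Group comparisons (`group_stats`)

One-way fixed-effects ANOVA is computed from explicit between/within sums
of squares (the mean square and df feed Duncan's test), with the p-value
from the F distribution. Duncan's multiple range test uses studentized-range
quantiles evaluated numerically from `scipy.stats.studentized_range` at the
protected level `1 − (1 − α)^(r−1)` for a range of `r` means — no table
interpolation — validated in tests against published 5% table values at
df = 10 and 20. The least significant range is `q × sqrt(MS_within / n_h)`
with `n_h` the harmonic-mean replicate count (exact for balanced designs,
a documented convention otherwise). A pair differs only if every enclosing
range of sorted means is significant (the containment rule), which keeps
homogeneous sets contiguous; compact letters are the maximal homogeneous
runs, lettered "a" onward down the sorted means. α defaults to 0.05 and is
a parameter throughout.

Depth contrasts use Welch's two-sample t (robust to depth-wise variance
differences; the pooled variant is not assumed). Two identical constant
samples return p = 1, unflagged. No normality checks or transformations
are applied before ANOVA, matching the published analysis.

## Synthetic data (`synthetic_data`)

The generator emulates the factorial layout — 5 treatments (CK, NPS0–NPS3)
× 2 depths × 3 sampling days (30/90/150) × 3 replicates = 90 records — and
injects treatment/depth/day effects multiplicatively **at the biomarker
level** (GlcN and MurA for the microbial channel; V/S/C phenols for the
plant channel), so the conversion equations are genuinely exercised.
Because the conversions are linear, a biomarker-level multiplier maps to
exactly the same pool-level multiplier; the zero-noise pass-through test
asserts this to 1e-9.

Defaults are the package's statement of the study conditions:

- NPS3 : NPS1 pool ratios fixed exactly at 1.053 (MNC, topsoil), 1.139
  (MNC, subsoil), 0.930 (PNC, topsoil), 0.837 (PNC, subsoil).
- Baselines chosen once at realistic cropland magnitudes for the region
  modeled (topsoil SOC 16 mg g⁻¹, subsoil 10 mg g⁻¹) so that MNC/SOC sits
  near 55%/48% and PNC/SOC near 27%/26% at mid-season, inside the reported
  seasonal ranges; day multipliers move MNC up and PNC down over the season.
- Noise is multiplicative lognormal with unit mean
  (σ² = ln(1 + cv²), μ = −σ²/2), guaranteeing positivity and unbiased
  group means. The replicate-level dispersion of such trials is not pinned
  down by published summaries; `noise_cv = 0.1` is a plausible placeholder,
  and results quoted from simulations state it.
- Covariates (AN, SAP, SM, five hydrolases) get treatment-monotone means
  (e.g. available P rising NPS0→NPS3) purely for interface completeness.

What passing tests show: the arithmetic, the statistical machinery and the
pipeline plumbing are correct, and configured effects are recovered
unbiasedly (mean recovered NPS3-vs-NPS1 effects over 1,000 experiments
within 1 percentage point at cv = 0.1, n = 3). What they do not show: the
generator has no spatial structure, no inter-biomarker correlation beyond
the shared channel multiplier, and no community composition, so agreement
with it says nothing about field measurements themselves.

## Problem sizes

The default verification runs use 10,000 null ANOVA simulations
(5 groups × 3 replicates) for the α-calibration check and 1,000 simulated
experiments for effect recovery; both complete in seconds and the Monte
Carlo error at these sizes (≈ ±0.004 on the rejection rate, ≈ ±0.1 pp on
recovered effects) is well inside the tolerances asserted.

## Known limitations

- The 30% humification efficiency is a bookkeeping assumption, not a
  kinetic model; no solution chemistry (pH, ionic strength) is modeled.
- Conversion coefficients (45, 9, 0.33/0.90/1.00, 0.08) are treated as
  exact; alternative amino-sugar corrections from the literature are not
  adjudicated.
- Duncan's test is implemented as published convention dictates; no
  assumption checking or multiplicity philosophy beyond it is offered.
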