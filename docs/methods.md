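# Methods

## Scope and model structure

`feedcast` models the finishing phase of feedlot cattle around a single
biological endpoint: the shrunk body weight an animal will carry when its
empty body reaches a target fat fraction (default 28 % empty body fat, EBF,
the composition associated with the USDA low Choice grade). That endpoint
weight — the adjusted final shrunk body weight, AFSBW — is estimated two
independent ways, and the disagreement between the two routes is what the
genomic layer tries to explain.

### Body-composition routes

**Hip-height route (HH).** Hip height (cm) and age (d) give a BIF frame
score through sex-specific polynomials (valid for ages 150–640 d; outside
that window the package warns and extrapolates). AFSBW is then a linear
function of frame score with one line per sex class (bull 40·FS + 440,
steer 33.4·FS + 366.6, heifer 26.7·FS + 293.2, kg). Steers use the *male*
frame-score polynomial and the *steer* AFSBW line; the distinct steer line
is the reason the male polynomial can serve both bulls and steers. Frame
score is deliberately not clamped to its nominal 1–9 scale — the AFSBW
lines are linear and tolerant, and clamping would create artificial mass
points; out-of-range scores are logged.

**Carcass-trait route (CT).** EBF (%) comes from fat thickness, hot carcass
weight and marbling, with a ribeye-area term when REA was measured (full
equation) and without it otherwise (reduced equation); the route records
which equation was applied per animal. Empty body weight is
EBW = 1.316·HCW + 32.39 kg, and

    AFSBW_CT = (EBW + 14.26 · (28 − EBF)) / 0.891,

i.e. 14.26 kg of empty body weight per percentage unit of EBF separates the
animal from the target composition, and 0.891 converts empty to shrunk
weight. The target EBF is a configuration parameter because the low-Choice
endpoint is not a biological constant across sexes and breed types. EBF is
not clamped before the correction.

### Net-energy growth engine

The engine is a transparent NRC-2000-level implementation. The commercial
growth model whose role it plays documents weather-driven maintenance
adjustments and an exponential-decay adjustment for gain composition whose
internals are not public; this package deliberately substitutes the
published NRC core with a constant environment, exposing a single
multiplicative `maintenance_factor` (default 1.0) instead. The chosen
anchors justify the substitution: at the default diet ME of 3.2 Mcal/kg the
cubic ME→NE conversions give NEg = 1.51 ≈ 1.5 and NEm = 2.19 ≈ 2.2 Mcal/kg,
the densities the analysis assumes.

Daily energy budget (all Mcal/d, weights kg, intakes kg DM/d):

* maintenance requirement `NEm_req = 0.077 · SBW^0.75 · maintenance_factor`;
* size scaling through the equivalent shrunk weight
  `EQSBW = SBW · SRW / AFSBW` with standard reference weight SRW = 478 kg
  at 28 % EBF — an animal with a large mature size behaves like a lighter
  (leaner-gaining) animal at the same scale weight;
* retained energy `RE = 0.0635 · (0.891·EQSBW)^0.75 · (0.956·ADG)^1.097`,
  where 0.956 converts shrunk-weight gain to empty-body gain.

The forward gain predictor inverts this budget analytically:
feed above maintenance supplies `RE_avail = (DMI − NEm_req/NEm) · NEg`, and

    EBG = (RE_avail / (0.0635 · (0.891·EQSBW)^0.75))^(1/1.097),  ADG = EBG/0.956.

Using the exact algebraic inverse (rather than the conventional rounded
power-law constants 13.91/0.9116/0.6837) makes the forward gain equation
and the backward intake calculation mutual inverses to machine precision,
which the test suite asserts at 1e−6; the rounded published constants agree
with the exact inverse to within ~0.5 %. Intake at or below maintenance
returns zero gain with a warning — weight loss is out of scope.

Forward projection walks one-day explicit Euler steps from entry weight:
DMI from a pluggable predictor (default the NRC empirical form
`DMI = SBW^0.75 (0.2435·NEm − 0.0466·NEm² − 0.0869)/NEm`), gain from the
inverse budget, stop at the first day SBW ≥ AFSBW (cap 1,000 d, then an
error). The days-on-feed output is that integer day; mean DMI and ADG over
the horizon are returned with it. An alternative end-BW-keyed empirical DMI
predictor (`end_bw_dmi`, evaluated at final BW with a maintenance-available
energy density of 2.2 Mcal/kg) is provided behind the same pluggable
interface; it is an in-package stand-in, not a published equation, and is
labelled as such.

Two scalar statistics complete the engine. The expected days on feed
`eDOF = (AFSBW_CT − iSBW)/oADG` uses the observed gain and the carcass
endpoint, eliminating intake-model uncertainty. The dry matter required
(DMR) runs the budget backward over the observed feeding period with SBW
advancing by the observed ADG:
`DMR_day = NEm_req/NEm + RE/NEg`, reported as the period mean. By
construction `RE/NEg + NEm_req/NEm = DMR_day` exactly (energy conservation
is asserted per day in the tests).

### Genomic adjustment

Eleven molecular breeding values (MBVs — summed allele-substitution scores
from commercial SNP panels trained on marbling, REA, ADG, HCW and RFI) and
the nine-level UASMS2×E2FB leptin genotype class are the candidate
explanatory variables. Delta variables are exact subtractions
(ΔAFSBW = AFSBW_CT − AFSBW_HH, ΔDOF = eDOF − DOF_route,
ΔDMI = DMR − DMI_HH, Δ ADG = observed − predicted); missing operands
propagate as missing, never as zeros.

Four published coefficient sets are shipped as constants (`EQ9`–`EQ12`) and
as pure-arithmetic appliers; the corresponding *forms* can be refitted by
OLS on any cohort. The sex indicator is a = 0 for steers, 1 for heifers
everywhere. Fitting is ordinary least squares (statsmodels); the original
analysis used REML mixed models for the classificatory comparisons, but no
random-effect structure is described, so fixed-effects least squares is
used throughout and documented as a simplification. Reported RMSE is
`sqrt(SSE/(n−p))` and r² the ordinary coefficient of determination.

Stepwise selection is the classic forward-entry (smallest partial p below
`entry_p`, default 0.15) with backward elimination (largest p above
`stay_p`, default 0.15) loop — the defaults of the statistical package the
field conventionally uses. Ties are broken by candidate order, making the
procedure deterministic; an exclusion list (by default
{leptin_class, mbv_rea}, which are collinear because the leptin SNPs are
part of the REA panel) bars one member while the other is in the model. An
exhaustive best-subset search (BIC) is provided as an independent oracle
for small candidate pools.

Leptin statistics: allele counts C = 2·CC + CT, T = 2·TT + CT, the C:T
ratio, and Pearson χ² (df = 2) of the genotype counts against the 25:50:25
expectation. Note a labelling tension in the source material: the
heifer-labelled genotype counts yield C:T ratios of 1.24 (E2FB) and 2.46
(UASMS2) — ratio of ratios 1.98 — while the accompanying text attributes
those numbers to steers (whose counts give 1.43 and 2.15, ratio 1.51). The
functions consume raw counts and take no side; the package's reference
checks use the printed counts.

### Adequacy statistics

Population moments (divide-by-n) are used so the MSEP decomposition is an
exact partition:

    MSEP = (mean P − mean O)² + (sd_P − r·sd_O)² + (1 − r²)·sd_O².

The systematic-bias form `(sd_P − r·sd_O)²` is the Bibby–Toutenburg
partition. Because "mean bias" is reported in the literature sometimes as
the signed mean difference and sometimes as its square, both are returned,
labelled (`mean_diff` vs `mean_bias_sq`). Accuracy is computed directly as
`Cb = 2·sd_O·sd_P / (sd_O² + sd_P² + (mean O − mean P)²)` and concordance
as `CCC = r·Cb`, which keeps Cb ∈ (0, 1] even when r ≈ 0. Zero-variance
inputs flag the correlation-based statistics as undefined rather than
raising.

Cross-validation: each replicate draws `train_n` rows (default 750) without
replacement, refits the model form on them, and scores the adequacy panel
on the held-out remainder; 2.5 %/97.5 % quantiles over replicates use
linear (type-7) interpolation. One direction per replicate is evaluated —
with k = 2 the "sample-size-weighted average over folds" of the original
description reduces to essentially this, and the train/test sizes (750/749
at the reference cohort size) differ by one row. Per-replicate substreams
are spawned from a single `SeedSequence`, so runs are bit-reproducible
under a fixed seed and replicates are independent.

## Synthetic cohort generator

The generator is the package's stand-in for the commercial feedyard
database (681 heifers, 836 steers; the complete-case analysis set is
1,499). It emulates three published layers of structure and nothing more:

1. **Marginals** — per-sex mean, SD and range for 9 performance/carcass
   traits and 11 MBVs. Each is a truncated normal whose *latent* location
   and scale are solved (2-d root find on the analytic truncated-normal
   moments) so the truncated distribution matches the printed mean and SD;
   the printed ranges are hard bounds. Marbling is additionally rounded to
   the integer 3–9 scale, and its latent variance is pre-shrunk by the 1/12
   rounding variance so the discretized score still matches the printed SD.
   Without the moment matching the marbling mean would be off by ~0.12 —
   the truncation at 3 is strongly asymmetric.
2. **Correlations** — a Gaussian copula over the latent normals. The
   defaulted nonzero entries are the published MBV×phenotype correlations
   (hip height, final BW, HCW, fat thickness, marbling, REA, DOF per MBV)
   plus a documented handful of phenotype–phenotype values (HCW–finalBW
   0.85, iSBW–finalBW 0.60, iSBW–HH 0.55, iSBW–DOF −0.55, finalBW–ADG 0.45,
   finalBW–DOF 0.20, ADG–DOF −0.35, HCW–REA 0.45, FT–marbling 0.35) chosen
   once as field-plausible; all other pairs, including MBV–MBV, default to
   zero because no source values exist. The assembled matrix is not quite
   PSD (minimum eigenvalue ≈ −0.39) and is repaired by eigenvalue clipping
   with renormalization, with a warning; the repair perturbs the targeted
   entries mildly (the REA–MBV_REA correlation of 0.370 is reproduced
   within ±0.01 at large n).
3. **Genotypes** — UASMS2 and E2FB drawn independently per SNP from the
   per-sex genotype counts, normalized. Genotypes are independent of the
   continuous MBVs by default; an optional coupling switch shifts `mbv_rea`
   by a configurable amount per C allele, mimicking the observed ordering
   of REA-MBV means across leptin classes.

**Generating truths.** With `truth="eq9"` (or eq10/eq11/eq12) the
corresponding response is simulated as the published mean function plus
Gaussian noise at the published residual SD (51.3, 49, 1.11, 1.17
respectively). For the DMR truths, predicted DMI is first produced by the
engine's empirical model (at the mid-period SBW for the model route, at
final BW for the end-BW route) so the regressor has realistic spread. For
the AFSBW truth, the hip-height AFSBW is computed from the generated hip
heights through the composition module, exactly as the pipeline would.
Because no SD is published for AFSBW_CT (a derived quantity), the optional
`target_total_sd` calibration rescales the systematic part around its mean
so the total response SD equals a requested value — 65.7 kg, back-solved
from RMSE 51.3 and r² 0.39, is the value used in the calibration checks,
and the applied scale factor is recorded in the truth report.

Randomness flows from one `numpy` Generator per `generate()` call with a
fixed variable order, which makes cohorts bit-reproducible under seed; the
per-animal-substream idea was dropped as needless given vectorized
generation (determinism is what matters, and it holds).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: the full phenotype correlation matrix (most
pairs are zero by default), MBV–MBV dependence, linkage between the two
leptin SNPs, any genotype–phenotype association beyond the optional
coupling switch, pen/management structure, seasonal environment, and the
identity finalBW = iSBW + ADG·DOF (all marginals are drawn, so the
bookkeeping identity holds only in correlation, not exactly). Recovery
tests on truth cohorts validate the estimation machinery, not the
biological truth of the published coefficients.

## Numerical choices

* Double precision throughout; published coefficients stored to full
  printed precision.
* Day loops are explicit Euler with a 1-d step; DOF is the first day the
  target is met (integer ≥ 1), so `AFSBW = iSBW + ε` gives 1 d.
* The truncated-normal moment match caches solutions per (mean, sd, lo,
  hi); a failed solve falls back to the nominal parameters with a warning.
* Stepwise ties are broken by candidate list order; the selection is
  invariant to candidate ordering when no ties occur (tested).
* Quantiles: linear/type-7 interpolation (numpy default), documented
  because replicate-quantile intervals are a headline output.
* CSV round-trips use `float_precision="round_trip"` on read so
  write→read→write is byte-identical.

## Problem sizes in the shipped checks

Replicate recovery runs use 200 cohorts of n = 1,499 (673 + 826); the
calibration cohort for the heifer-ADG check uses n = 10,000; cross-
validation property checks use 60–200 replicates at train_n = 750. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances (e.g. ±0.2 kg on the mean recovered 44.5 kg coefficient over
200 cohorts).

## Known limitations

* The growth engine is an NRC-core stand-in: no weather, mud, implant or
  ionophore effects, no gain-composition decay adjustment, no weight-loss
  modelling.
* Fixed-effects OLS replaces REML mixed models; standard errors ignore any
  within-pen correlation a real feedyard would have.
* The end-BW DMI predictor is a documented stub, not a published equation;
  conclusions that depend on its exact form (the eq12-route coefficients
  excepted, which are recovered from its own truth) should not be drawn.
* Leptin class is modelled as nine unordered levels; no additive allele
  coding is provided.
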