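# Methods

## The question being simulated

A mapping centre following current consensus practice recruits ≥15
healthy volunteers, computes mean ± 2 SD of their global myocardial T1
(or T2) values, and uses that interval as its normal range. Because
normal values differ by sex and by scanner, the *composition* of those
15 volunteers is a hidden driver of diagnostic accuracy. The package
estimates, for a healthy group G and a reference recipe R, the
distribution over recruitment draws of

accuracy(r) = (1/|G|) · #{ g ∈ G : x̄(r) − 2·s(r) ≤ g ≤ x̄(r) + 2·s(r) },

where r is a 15-value sample from R's pool, x̄ and s its sample mean
and SD (n−1 denominator), and the bounds are inclusive. 20,000
independent draws are summarised as median (Q1–Q3) percent. Per-draw
accuracies are exact multiples of 100/|G|, which is why published
medians sit on coarse grids (e.g. 4% steps for a 25-subject group).

Conventions (each switchable): SD uses the n−1 denominator; bounds
are inclusive (`strict=True` gives the open interval); the evaluation
group is the full cohort, including subjects that happened to enter
the reference draw — the target quantity is performance of a local
range on the healthy population that produced it, not out-of-sample
error (`leave_out=True` in the loop engine gives the sensitivity
variant). Medians of the 20,000 draws use the midpoint-of-central-
order-statistics convention; printed cells round half away from zero.

## Reference-pool recipes

- `male_only` / `female_only`: that sex's full cohort.
- `mixed_balanced`: the larger sex is subsampled without replacement
  down to `min(count, balance_cap)` and concatenated with all of the
  smaller sex; the subsample is redrawn on *every* Monte Carlo
  iteration. For the 57M/35F cohort the cap is 35 (pool of 70,
  35 + 35); the 25/25 cohort needs no cap.
- Cross-scanner scenarios use the *other* scanner's cohort as the pool
  and the column's cohort as the evaluation group. The source text
  does not state the direction explicitly; this reading reproduces all
  eight published cross-scanner medians under the Gaussian model, so
  the package adopts it (it remains an interpretation).

T2 maps exist only for one scanner, so cross-scanner T2 cells are
structurally absent.

## The synthetic cohort generator

Raw per-subject values from the original cohorts are not public. The
generator emulates them from the published summary statistics, which
suffices because every downstream quantity depends on the cohorts only
through the per-subject global values, whose normality the original
analysis confirmed:

- Global values: subject latent value
  μᵢ = map_mean + hr_effect·(HRᵢ − hr_mean) + εᵢ with
  εᵢ ~ N(0, map_sd² − hr_effect²·hr_sd²), so the marginal is exactly
  N(map_mean, map_sd²) while a linear heart-rate effect (ms per
  beat/min, per the published regression: 0.672 and 0.943 for the two
  T1 cohorts, −0.074 for T2) is recoverable by regression. The
  feasibility invariant hr_effect²·hr_sd² ≤ map_sd² is enforced.
- Segments: each of `n_slices × 6` AHA-style sectors gets
  μᵢ + offset + N(0, segment_noise_sd²). The mid-ventricular septal
  sectors (anteroseptal/inferoseptal on slice ⌊n_slices/2⌋) are
  shifted by −septal_offset_frac·μᵢ and the remaining sectors
  compensated upward so the subject mean stays μᵢ. The contrast form
  was chosen deliberately: it makes the measured septal-vs-global
  percent difference equal the configured fraction (defaults 0.78%
  female, 0.32% male, emulating the partial-volume deficit) *and*
  keeps the cohort grand mean at map_mean; an uncompensated shift
  can do neither at once on a single-slice cohort.
- Artefacts: independent Bernoulli flags per segment at the cohort's
  configured rate (defaults 13.2/12.4% male/female for the older
  scanner, 6.1/10.5% for the newer), with an optional per-label weight
  vector for location structure (uniform by default; locations in the
  source are figure-only and are therefore configurable, not fixed).
- Demographics: Gaussian height/weight/heart rate at the published
  means/SDs; ages from a Gaussian truncated at 18; BMI derived.

What the generator does *not* emulate: pixel-level map formation,
correlated artefact clusters, non-Gaussian tails, within-subject slice
trends, and any true covariance between demographics and mapping value
beyond the heart-rate term. Passing tests therefore demonstrate the
statistical behaviour of mean ± 2 SD ranges under the published
summary conditions, not properties of any real scanner.

Free parameters not identifiable from published summaries:
`segment_noise_sd`, the within-subject segment SD, defaults to 3 ms
for T1 and 0.3 ms for T2 — roughly 15% of each map's between-subject
SD. It inflates the realised global SD by only
segment_noise_sd²/(accepted segments), ≈ 0.1% relative at the
defaults, so the marginal calibration is unaffected. `n_slices`
defaults to 1 for the single-slice cohort and 3 for the whole-heart
cohorts and is configurable because the original slice counts per
subject are not stated.

## Quality control

Artefact-flagged segments are excluded; the global value is the
unweighted mean of the rest; subjects losing every segment are dropped
and reported, never raised. The QC report conserves counts (per-label
exclusions sum to the total) and exposes the exclusion rate that the
source reports as 8.1% (187/2316).

## Validation strategy

- **Coverage oracle.** An independent brute-force path draws fresh
  Gaussian reference samples and evaluation values and measures
  coverage of mean ± 2 SD. The engine's mean accuracy on large
  single-Gaussian cohorts must agree within 1 point; in the
  large-reference-sample limit the oracle must approach
  Φ(2) − Φ(−2) = 95.45%.
- **Parameter recovery.** The generator's heart-rate slope and the
  between-sex gap are recovered by the OLS battery within their 95%
  CIs at the nominal rate.
- **Grid reproduction.** For each targeted cell, replicate synthetic
  studies are generated at the published summary statistics, the
  20,000-iteration Monte Carlo runs per replicate, and per-replicate
  medians are averaged. The original study had one fixed empirical
  cohort; averaging replicates removes the single-cohort sampling
  noise that the synthetic re-creation would otherwise add. The
  per-replicate median has SD ≈ 16 points for the noisiest cells
  (25-subject groups, 4% granularity), so the default acceptance run
  averages 2,000 replicates (SE ≈ 0.4 points) and the test suite 800;
  50 replicates already give a usable but noisier estimate. Agreement
  is required within ±6 percentage points — the Gaussian model's
  analytic cell values sit within ~5 points of every published
  same-scanner median, and the accuracy granularity of 100/n_eval
  contributes up to ±2 further points.

## Numerical choices

- Vectorised engine: simulations are processed in blocks of 4,000;
  without-replacement draws use row-wise rank tricks
  (`argsort` of uniform matrices). A pure-Python loop engine built
  from the scalar primitives (`make_pool → draw_reference →
  build_range → classify`) is kept as a cross-check.
- RNG: `numpy.random.Generator` throughout; one seeded generator per
  top-level call, child streams spawned per scenario/replicate via
  `SeedSequence.spawn`, no global state. Fixed seeds give
  bit-identical cohorts, grids and report bundles.
- Degenerate inputs: zero-SD specs generate exact constants; a
  zero-width range classifies only its own point as normal; the
  two-sample t on two zero-variance equal-mean groups returns p = 1 by
  convention; rank-deficient regression designs raise an error naming
  the collinear covariates.
- Statistics: Welch t by default (the source does not state pooled vs
  Welch; both exposed). Normality via Lilliefors by default, classical
  KS with estimated parameters available but conservative. Sex is
  coded male = 1, female = 0, so the sex coefficient is negative when
  females run higher — matching the sign convention of the published
  regression table.

## Known limitations

- Published regression coefficients and artefact-location χ² results
  cannot be reproduced exactly without the raw data; they are covered
  by recovery and calibration properties instead.
- Cross-scanner cells inherit the directionality interpretation above.
- The ±6-point grid reproduction is a stochastic comparison of a
  Gaussian re-creation against one empirical cohort's printed medians;
  2–5 point systematic offsets in individual cells are expected and
  observed (e.g. the opposite-sex 25-subject T1 cells average ≈ 59%
  against a printed 64%).
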