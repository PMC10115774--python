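# Methods

This note documents the models, numerical choices, and limitations behind
`tracerflux`, in the order data flow through the package.

## Isotope arithmetic

All mixing calculations use atom fraction, F = ¹³C/(¹²C+¹³C), because F is
the coordinate in which carbon mass balances are linear at any enrichment.
δ-notation mixing — the common natural-abundance shortcut — has a relative
bias of order (F_src − F_ref) and is badly wrong against a 0.99 atom-fraction
end member, so the package has a single mixing code path in F-space and the
δ-space helper (`delta_space_fraction`, provided only for natural-abundance
cross-checks) refuses inputs beyond |δ| = 100 ‰.

The ¹³C/¹²C ratio of VPDB is fixed at **R = 0.011180** by default. The
literature carries several VPDB ratio values differing in the 4th decimal;
the choice only shifts the δ↔F map, cancels in the two-source quotient to
first order, and is recorded in every output file's metadata (`r_vpdb`) so a
run is reproducible. It is configurable through `IsotopeStandard`.

Two-source fractions f = (F_mix − F_ref)/(F_src − F_ref) are **never
clipped**: values outside [0, 1] are genuine mass-balance diagnostics (noise,
priming, wrong end members) and are flagged downstream (`f_litter` window
[−0.05, 1.05]; tracer tolerance −1e−4) rather than silently hidden. A
separation threshold |F_src − F_ref| ≥ 1e−5 (≈1 ‰ at natural abundance, i.e.
instrument scale) guards against unidentifiable splits; the experiment's
design guarantees it because the C₄ litter (δ = −12.6 ‰) is always more
positive than soil-derived CO₂ (sites drawn around −27 ± 2 ‰, clipped to
≤ −20 ‰).

## Sealed-jar flux accounting

Jars (946 mL, 296.15 K, 1 atm) remain sealed between samplings and are
flushed with CO₂-free air afterwards, so a measured concentration is the
production over the half-open interval (previous sampling, sampling]. The
conversion is ideal-gas: CO₂-C µg = ppm·10⁻⁶ · PV/(RT) · 12.011·10⁶. The
soil volume (~1/1000 of headspace) is neglected and pressure fixed at
101,325 Pa — sub-0.2 % effects. Intervals above the 5000 ppm operating
ceiling, or with O₂ drawdown above 2.4 % of the initial 20.9 % (1:1
CO₂:O₂ stoichiometry), carry QC flags.

Sampling days are 4, 11, every 14 d through 151, 179, then every 28 d
through 571 (the published pattern — initial, biweekly for 140 d, monthly
after 179 d — does not print the exact dates; this grid matches it and ends
exactly at 571 d).

## Partitioning

Treatment triplets are paired by (site, point, depth); the N-addition arm
shares the un-amended control of its sampling point. A missing control falls
back to the site-mean control composition (mass-weighted, per interval) with
a `control_imputed` flag.

Mixing is applied **per interval** and component masses summed — the
intervals are the measured quantities. For the soil/litter split this is
algebraically identical to mixing the cumulative CO₂ once (both are linear);
for the tracer the two differ only through the slow drift of the unlabeled
background F_t2 in the denominator (F_label − F_t2), bounded by
(F_t2 − F_litter)/(F_label − F_t2) ≈ 1.6e−4 relative. The equivalence test
asserts exactly these two tolerances.

The same bound is the only systematic error of the tracer formula itself,
which is why noise-free end-to-end recovery is asserted at 0.01 percentage
points rather than machine precision.

**Litter correction.** The unlabeled jar contains a natural-abundance Cβ
pool that the soil/litter split cannot distinguish from litter (identical
δ). Since the labeled and unlabeled lignins are chemically identical, the
labeled-jar Cβ estimate is subtracted from the litter component before
accumulation (`correct_litter_for_cbeta=True`). The raw additive split
(`litter_c_raw`, with soc + litter_raw = total exactly) is kept alongside so
mass balance remains auditable. Without the correction the litter estimate
would carry up to ≈0.2 pp of tracer-pool carbon.

Cumulative checkpoints (183, 365, 571 d) report the **effective day** — the
last interval boundary at or before the checkpoint — and ground-truth
comparisons are made at identical coverage.

## Field litterbags

Bags hold 4.5 g soil with the same 250:25:1 amendment, so initial masses
scale ×4.5 (litter C 188,550 µg; Cβ 1188 µg). Labeled bags sit at odd,
unlabeled at even sampling points, so the reference is the site-level
mass-weighted mean composition of retrieved unlabeled bags.

**New-C correction.** Because unlabeled bags experience the same
decomposition and the same new-C inputs as labeled bags, referencing the
unlabeled *endpoint* composition makes f_lignin · total_C unbiased without
any explicit mass subtraction (subtracting estimated new C as well would
double-correct; we verified this analytically and on synthetic truth). The
naive estimator — referencing the *initial* mixture composition — is
reported alongside; with new C more depleted than the mixture it
overestimates loss, and the tests assert that predicted sign. The residual
bias of the corrected estimator is the natural-abundance offset between the
unlabeled Cβ pool and the pooled background, ≈0.01 pp at 50 % loss.

Negative f_lignin beyond −1e−6 floors the remaining mass at zero
(`negative_f_lignin`); losses are clipped into [0, 100] % with a
`loss_clipped` flag. Sites with no retrieved unlabeled bag yield flagged
NaN rows (`reference_unavailable`) rather than silent exclusion.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:

* **Decay**: per-pool first order with a piecewise-constant rate multiplier.
  `DecayProfile.from_cumulative_loss` calibrates the base rate so the
  571-day integral reproduces a target cumulative loss exactly.
* **Calibration**: site-level cumulative losses are stratified log-uniform
  over 1.7–31.4 % (Cβ), 2.0–53.0 % (litter) and 6.3–99.0 % (SOC) — the
  spans the emulated study reports — with litter rank-coupled to lignin
  (shared driver) and SOC independent, reproducing the observed
  coupled/decoupled contrast. ~40 % of sites get a months-scale transient
  pulse shared by lignin and litter; SOC rates decline after day ~380.
  Sample-level log-normal jitter (σ = 0.15 on the rate integral) spreads
  points within sites; field site-mean Cβ losses span 9–63 % with σ = 0.2
  point jitter.
* **SOC pools**: 1–10 % C (log-uniform) on 1 g soil. Fast-SOC sites can
  exceed 5000 ppm in the longer intervals; the simulator warns and the flux
  stage flags those intervals (the real protocol avoided this by sampling
  more often — the fixed grid here keeps schedules comparable).
* **N addition** is a multiplicative rate modifier calibrated per jar so the
  *cumulative additive* effects equal +1.6 pp (lignin) and +6.2 pp (litter),
  matching how the effect is reported. The stated N dose is metadata only.
* **Noise**: Gaussian, δ s.d. 0.2 ‰ and CO₂ relative s.d. 1 % — conventional
  tunable-diode-laser/IRMS precision; the emulated study does not state
  instrument precision, so these defaults are flagged as conventional.
  Priming (a ‰ shift of soil-derived CO₂ in amended jars) is available to
  characterize partition bias, which grows monotonically with the shift; it
  is a documented property, not a correction.
* **Ancillary tables** plant recoverable structure: exact mineralization
  increments; rare ASVs (<10 counts) and low-depth samples (≤900); Chao1
  residuals orthogonalized against [1, √depth] so OLS returns them exactly.
  Retained samples keep >900 sequences within retained ASVs, which is the
  condition under which the fixed sample-then-ASV filter order is
  idempotent.

One `numpy` Generator seeded from `SimulationConfig.seed` drives everything;
identical seeds are bit-identical, and field/ancillary streams use spawned
child seeds so the stages are independently reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: microbial community dynamics and priming as
mechanisms (priming is an imposed shift, not emergent), temperature/moisture
responses, within-jar spatial structure, non-first-order kinetics beyond
piecewise multipliers, respiration fractionation (end members equal bulk
substrate δ; a config hook exists), and depth effects on litter decay.
Recovery results demonstrate the *estimators* are correct under the stated
measurement model, not that the measurement model captures every field
process.

## Ancillary statistics

* Net N mineralization: signed Δ(NH₄⁺-N + NO₃⁻-N) for pairs 9−1, 18−9,
  18−1 months; the telescoping identity is tested.
* Filters: samples ≤900 sequences dropped first, then ASVs with grand total
  <10 across remaining samples (order as stated and tested; boundary
  semantics exact: 900 is dropped, 10 is kept).
* Chao1: classic S_obs + F1²/(2F2); when F2 = 0 the bias-corrected
  S_obs + F1(F1−1)/(2(F2+1)). Cross-checked against scikit-bio. The
  variant choice is undocumented in the emulated analysis; this convention
  is recorded here.
* Chao1 residual: OLS of Chao1 on √(total sequences) via `numpy.lstsq`
  (residuals mean-zero; ≥3 samples required). Richness is computed at the
  ASV level by default.
* Hellinger: √(count/row total); unit rows; Euclidean distance on the
  transform equals Hellinger distance (brute-force oracle in tests).

## Problem sizes and determinism

The acceptance script and test suite run the full pipeline at 20 sites ×
8 samples (noise-free recovery), 25 sites × 8 (200-replicate noisy bias),
20 field sites × 16 bags, and 1000 random mixtures for the algebra oracle —
sizes chosen so the whole validation completes in seconds while every
estimator sees its full operating range. All stochastic tests are seeded;
hypothesis suites run derandomized.

## Known limitations

* The tracer denominator (F_label − F_t2) inherits the ~1.6e−4 relative
  end-member offset discussed above; at the reported precision this is
  negligible but it is why "exact" recovery claims stop at 0.01 pp.
* The field correction assumes new C enters labeled and unlabeled bags at
  the same site with the same composition and amount in expectation;
  site-scale heterogeneity beyond the modeled point jitter would appear as
  scatter, not bias, in the site mean.
* Cumulative curves may decrease locally under noise because negative
  interval fractions are retained (by design); QC flags make this auditable.
* The statistical modeling downstream of the percentages (mixed models,
  random forests, ordination) is intentionally out of scope.
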