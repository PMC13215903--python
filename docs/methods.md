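# Methods

This note documents the statistical procedure implemented in `cyclefda`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Data model and indexing

Input is one row per sampled calendar day per cycle
(`cycle_id, calendar_day, fsh, inhibin_b`), FSH in mIU/ml, inhibin B in
pg/ml, calendar day 1 = first day of menses. Cycles must have ≥15 sampled
days; missed draws appear as gaps or `NA` fields.

Day 0 of each cycle is the day of the mid-cycle ovulatory inhibin B peak:
the argmax of inhibin B inside a search window defaulting to the central
50% of the sampled span ("mid-cycle" is otherwise unquantified), with ties
broken to the earliest day. A `day0_override` column can pin day 0 for a
cycle when external information (e.g. sonography) should take precedence.

Missed interior days are filled by linear interpolation between the
nearest sampled neighbours and flagged; flags propagate to all outputs.
Interpolation never extrapolates: grid days outside a cycle's sampled span
are dropped. The analysis grid is the intersection of the per-cycle day
ranges, which with daily sampling of 25–28-day cycles lands near
day −13..+9 — the natural analysis span for cohorts of this design.

## Elastic registration

Curves on the common grid are mapped to [0, 1] and linearly up-sampled to
a working resolution of 101 points (a compromise: fine enough that the
dynamic-programming lattice resolves sub-day phase shifts of daily data,
coarse enough that a full cohort registration takes milliseconds).
The square-root velocity transform q = sign(f′)√|f′| (central differences;
one-sided at the boundaries; derivatives below 1e-10 of the value scale
zeroed so constant curves map to q ≡ 0) converts the Fisher–Rao metric to
the L² metric, with warping acting as q ↦ (q∘γ)√γ′.

Pairwise alignment minimises ∫(q₁ − q₂(γ)√γ′)² ds by dynamic programming
over monotone lattice paths with local steps
(1,1),(1,2),(2,1),(1,3),(3,1),(2,3),(3,2) — slopes between 1/3 and 3,
strictly monotone by construction. Segment costs use a right-endpoint
Riemann rule with γ locally linear; cost ties resolve to the
earlier-listed step, so degenerate all-zero SRVFs return the identity
warp. An optional dimensionless roughness penalty
(`penalty · ⟨q₁²⟩ · (√γ′ − 1)²` per unit length) is available and defaults
to 0 (pure elastic matching). On grids with ≤6 points the DP optimum is
exactly the brute-force optimum over all monotone paths with the same step
set; this is enforced in the test suite.

Group alignment iterates a Karcher-mean template: average the SRVFs of the
currently aligned curves, re-align every original curve to that template,
re-centre the warps so their mean is the identity (fixing the phase
gauge), and stop when the relative change of the summed elastic distance
falls below 1e-6 or after 20 iterations. An iteration that would increase
the objective (possible at finite grid resolution) is discarded and the
previous iterate kept, so the convergence trace is non-increasing by
construction.

Two registration choices deserve emphasis:

- **Scale-invariant warp estimation.** Warps are estimated on
  unit-L²-norm SRVFs. Ovulatory peak heights vary several-fold between
  cycles, and without the normalisation the DP partly uses the √γ′ factor
  to chase amplitude rather than phase ("pinching"), which can *reduce*
  inter-cycle correlation for already well-aligned cohorts. Amplitudes of
  the output curves are untouched.
- **Shared warps across hormones.** By default the warps estimated on the
  inhibin B curves are applied to both hormones of a cycle. FSH and
  inhibin B are measured in the same daily blood draw, so a cycle has one
  physiological time axis; registering the hormones independently deforms
  the two series differently and scrambles exactly the within-cycle
  cross-hormone lag structure the downstream analysis measures (in
  simulation, the early-window suppression signature survives shared-warp
  registration in 50/50 cohorts but only ~40/50 with independent warps —
  worse than no registration at all). Independent registration remains
  available (`shared_warps=None`), as does borrowing FSH-derived warps.

Alignment operates on raw-concentration curves; standardization happens
afterwards.

## Summary curves and uncertainty

Each cycle's aligned values over the common grid are z-scored with the
cycle's own mean and sample SD (denominator n−1; configurable). The
cohort summary is the per-day arithmetic mean across cycles (days covered
by fewer than two cycles are dropped and reported). Confidence bands are
percentile-bootstrap intervals: whole cycles are resampled with
replacement (cycles, not days, are the exchangeable units when each day
holds only a handful of values), per-day means recomputed, and the
(1−level)/2 and 1−(1−level)/2 quantiles taken per day. Defaults: level
0.95, 10,000 replicates, seeded and recorded in output metadata. With
four cycles the bootstrap distribution of a per-day mean has at most 4⁴
distinct values; this small-sample coarseness is inherent to the
percentile method and is reported, not smoothed away.

## Lag correlation analysis

A delayed effect of a leader hormone on a follower is measured on the
pair set {(leader(t), follower(t+k)) : t ∈ window, both present}, k ≥ 1,
window bounds quoted on the leader's day axis. On a −13..+9 grid the
whole-cycle window keeps 22 lag-1 pairs and the early-follicular window
−13..−8 keeps 6. Coefficients: Pearson r (p from the t-distribution on
n−2 df), Kendall τ-b (exact null for n ≤ 10 when tie-free, else the
normal approximation — exact enumeration is undefined with ties), and
Spearman ρ computed as Pearson on average ranks (exact permutation null
for n ≤ 8 — full enumeration beyond 8! permutations costs more than the
approximation error it removes — else the t-approximation). All p-values
are two-sided; no multiple-testing correction is applied (raw p-values
are the convention for exploratory lag analyses of this size; a Holm
adjustment can be applied downstream by the caller). The lag scan
evaluates a set of translations (default {0,1,2,3}) and reports the
argmax/argmin lags, ties resolved to the smallest |k|.

## Synthetic cohorts

The generator is phenomenological — it reproduces the statistical
structure the pipeline assumes, not follicle-population mechanics (no
follicle counts or sizes, no E2/LH/P/inhibin A, no intra-day
pulsatility). One cycle is built as:

- **Early follicular phase** (menses to day −8): the coupled delayed map
  B(t+d) = b_B + g₁(FSH(t) − b_F), FSH(t+d) = b_F − g₂(B(t) − b_B) with
  d = 1 day and default gains g₁ = 40 pg/ml per mIU/ml, g₂ = 0.02 mIU/ml
  per pg/ml. The linearised map has spectral radius √(g₁g₂) ≈ 0.894 — a
  damped saw-tooth with a 4-day period whose visible oscillation has
  faded by about day −6. A stability guard rejects parameterisations with
  radius above a configurable bound (default 1.0). With either gain zero
  the loop is open and the early phase sits at baseline.
- **Peri-ovulatory phase** (−8..0): inhibin B declines linearly to a
  nadir at day −2 (35% of its baseline), then rises to an ovulatory peak
  at day 0 drawn uniformly from 66.6–398.9 pg/ml; FSH declines to a
  trough near day −4 and peaks at day −1 at a level drawn from 6.6–9.3
  mIU/ml. Each cycle's whole amplitude scales with its drawn peaks
  (emulating the several-fold heterogeneity of follicular waves of ~4–14
  follicles), which also guarantees by construction that the day-0 and
  day −1 maxima are global.
- **Luteal phase**: both hormones low (inhibin B falling from ~35% to
  ~20% of baseline, FSH recovering toward baseline).
- **Phase jitter**: a smooth boundary-fixed sinusoidal warp of the
  follicular segment (SD 0.6 days) — the same family the registration
  estimates, making "alignment recovers the jitter" a well-posed test.
  The day-0 endpoint is fixed, so the ground-truth peak day survives.
- **Noise and missingness**: multiplicative lognormal noise with CV 8%
  (typical immunoassay scale; concentrations stay positive), and sample
  days deleted at rate 0.02 (≈2 missing samples per 4-cycle cohort,
  matching the study design), never on days −2..0. Under noise the
  injected day-0 peak is kept the strict maximum so the truth record
  remains well defined.
- **Reproducibility**: per-cycle spawned substreams of a seeded
  generator; a fixed (params, n_cycles, seed) triple yields byte-identical
  CSV output.

The oscillation amplitude (initial FSH excursion 1.2 mIU/ml before
amplitude scaling) is calibrated qualitatively — no quantitative amplitude
for the early-follicular saw-tooth is published.

**What passing tests show, and don't.** The closed-loop tests demonstrate
that the pipeline recovers a known 1-day-delayed feedback structure from
noisy, phase-jittered, amplitude-heterogeneous 4-cycle cohorts of this
design. They do not validate the biological model on real serum data: the
generator's regime change is a hard switch, its noise is day-independent,
its phase variation is low-order smooth, and real assay drift, luteal
dynamics and within-woman cycle dependence are not emulated.

## Numerical conventions and edge cases

- Day indices are integers; all windows are inclusive on both ends.
- Peak ties break to the earliest day; DP cost ties to the
  earliest-listed step (identity-biased); lag-scan coefficient ties to
  the smallest |lag|.
- Constant series raise a degenerate-SD error on standardization; zero
  variance in either correlation coordinate raises an error naming the
  coordinate.
- CSVs are written with `%.17g` and read with round-trip float parsing,
  so write→read cycles are bit-identical.
- The bootstrap, the simulation and the model `fit()` accept explicit
  seeds; the pipeline manifest echoes the config and hashes every
  artifact so deterministic stages can be verified bit-for-bit.

## Problem sizes used in the checks

Registration oracles run hundreds of ≤6-point exact DP-vs-enumeration
cases and 50 warp recoveries on 50-point grids; bootstrap coverage uses
500 Monte-Carlo replications of 20-cycle Gaussian cohorts with 2,000
resamples; rank-correlation oracles use 1,000 random small vectors; the
closed-loop recovery and alignment-benefit checks use 50 independently
seeded 4-cycle cohorts. These sizes give stable pass/fail behaviour for
the rates being tested (thresholds 90–95%) while keeping the whole suite
fast on a single CPU.

## Known limitations

- The elastic distance to a re-parameterised copy of a curve has a small
  discretization floor (a few percent of the curve's SRVF norm) from the
  DP's finite slope set; it shrinks slowly with resolution.
- Exact rank-statistic p-values are limited to tie-free n ≤ 10 (Kendall)
  and n ≤ 8 (Spearman).
- With four cycles, percentile bands are coarse (≤256 distinct resample
  means per day) and early-window coefficients (6 pairs) are individually
  noisy; cohort-level sign rates, not single-cohort magnitudes, are the
  reliable output.
- The generator's truth warp is defined on the follicular segment only;
  luteal-phase phase variation is not simulated.
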