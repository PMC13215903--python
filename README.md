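# cyclefda

Elastic functional data analysis of daily serum FSH and inhibin B levels
across individual ovulatory menstrual cycles.

## The scientific problem

During the follicular phase, pituitary FSH drives a wave of antral
follicles whose granulosa cells secrete inhibin B, which in turn suppresses
FSH — a candidate delayed positive–negative feedback loop ("FSH↔B").
Because each cycle's follicular wave differs in follicle number, stage and
timing, daily hormone series from different cycles are *out of phase*:
naively averaging them cancels exactly the oscillatory structure one wants
to see. `cyclefda` addresses this with the standard elastic
(Fisher–Rao/SRVF) registration machinery of functional data analysis:

1. **Indexing.** Each cycle's series FSH(t), B(t) is re-indexed to day 0,
   the day of the mid-cycle (ovulatory) inhibin B peak; missed sample days
   are linearly interpolated and flagged, and the cohort is restricted to
   the common day grid (typically about day −13 to day +9).
2. **Registration.** Curves are mapped to square-root velocity functions
   q(s) = sign(f′(s))·√|f′(s)|, under which the Fisher–Rao metric is the
   L² metric and time warping acts as q ↦ (q∘γ)·√γ′. Boundary-fixed
   monotone warps γᵢ are estimated by dynamic programming against an
   iterated Karcher-mean template; the warps estimated on the inhibin B
   curves (whose ovulatory peak is the sharpest landmark) are applied to
   both hormones of a cycle, since both come from the same daily draw.
3. **Summary curves.** Aligned values are z-scored per cycle,
   z(t) = (x(t) − x̄)/s, and averaged across cycles per day; uncertainty
   bands are nonparametric percentile-bootstrap intervals that resample
   whole cycles.
4. **Lag correlations.** A delayed effect of the leader hormone on the
   follower is measured on the pair set
   {(leader(t), follower(t+k)) : t ∈ window} with Pearson r, Kendall τ-b
   and Spearman ρ (two-sided p; exact small-sample nulls for the rank
   statistics). The FSH-leads contrast is evaluated over the whole common
   grid, the inhibin-B-leads contrast over the early-follicular window
   (day −13 to −8), and a lag scan over k ∈ {0,1,2,3} locates the
   best-synchronising translation.

Because daily per-cycle serum series of this kind are rarely deposited, the
package includes a first-class synthetic-cohort generator
(`cyclefda.simulate`) whose default preset encodes the published study
conditions: 25–28-day cycles sampled daily, an ovulatory inhibin B peak in
66.6–398.9 pg/ml at day 0, a pre-ovulatory FSH peak in 6.6–9.3 mIU/ml at
day −1, an inhibin B nadir at day −2, a damped saw-tooth produced by a
1-day-delayed linear feedback map in the early follicular phase, smooth
per-cycle phase jitter, multiplicative assay noise, and occasional missed
samples — with full ground truth for closed-loop testing.

## Worked example

```python
from cyclefda import HormoneFeedbackModel

res = HormoneFeedbackModel.from_simulation(seed=7, n_cycles=4).fit(seed=7)
print(res.summary())
```

```
Hormone feedback cycle analysis
================================================================
Cycles: 4    common day grid: [-13, 10]
Day 0 (ovulatory inhibin B peak) at S1: CD15, S2: CD17, S3: CD16, S4: CD15
Registration [fsh]: 4 iteration(s), warps shared, converged=True
Registration [inhibin_b]: 4 iteration(s), objective 0.7916 -> 0.2539, converged=True
----------------------------------------------------------------
    leader  lag     window    method    coef         p    n
       fsh    1  [-13, 10]   pearson   0.822  1.52e-06   23
       fsh    1  [-13, 10]   kendall   0.557  0.000196   23
       fsh    1  [-13, 10]  spearman   0.797  5.21e-06   23
 inhibin_b    1  [-13, -8]   pearson  -0.499     0.314    6
 inhibin_b    1  [-13, -8]   kendall  -0.200     0.719    6
 inhibin_b    1  [-13, -8]  spearman  -0.257     0.658    6
----------------------------------------------------------------
FSH-leads lag scan (Pearson): k=0: 0.568, k=1: 0.822, k=2: 0.642, k=3: 0.338
Max positive FSH-leads correlation at lag +1
```

Reading the output: the four simulated cycles share the day grid −13..+10
after peak indexing; the Karcher iteration reduced the elastic spread of
the inhibin B curves from 0.79 to 0.25 (those warps are shared with FSH).
Translating the standardized mean FSH curve forward by one day gives its
maximum positive correlation with the inhibin B curve (r = 0.82 at k = 1,
beating k = 0, 2, 3) — FSH leads B by one day — while in the early
follicular window the inhibin-B-leads coefficients are negative, the
signature of delayed suppression of FSH by inhibin B. Single-cohort
early-window coefficients are noisy with only 6 pairs; the sign is the
stable feature across cohorts.

A command-line interface mirrors the stages
(`cyclefda simulate | index | align | summarize | correlate | run |
validate`); `cyclefda run --out outdir` executes everything end-to-end and
writes per-stage CSV/JSON artifacts plus a manifest with SHA-256 hashes
for reproducibility checks.

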