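# Methods

## The pipeline

`hemorisk` fits a health-risk score to unlabelled five-analyte blood panels
(HTC, HGB, WBC, PLT, MPV). The pipeline is self-supervised: labels are
constructed from the data's own distribution, not from clinical annotation.

### Normalization and column statistics

Each analyte column is min-max mapped to [0, 1]: x ↦ (x − min)/(max − min).
This puts PLT (hundreds of 10⁹/L) on the same scale as MPV (≈10 fL) so that
no analyte dominates by magnitude alone. Held-out data is mapped with the
*training* (min, max); values then may fall outside [0, 1] and are
deliberately not clipped — the excess deviation is exactly the signal the
labeller uses. Column statistics use the population convention,
σ = √(Σ(x−m)²/N). The band-elimination and weighting stages consume these
normalized statistics, which makes the "normal band" data-driven rather
than a clinical reference interval: it adapts to whatever population the
table describes, and it will differ from lab reference ranges.

Pairwise analyte association uses the standard product-moment (Pearson)
correlation, grouped by gender (−1 female, +1 male) or by configurable age
bins (defaults 18–37 and 38–64). Groups with fewer than two records, or a
constant analyte, report their table as unavailable rather than raising.

### Band elimination

A record is eliminated iff all five normalized analytes lie inside
[m − a·σ, m + a·σ] (inclusive), where a ≥ 0 is the band half-width
multiplier (default 1). The AND-over-analytes rule means one abnormal value
retains the record. Consequences worth knowing:

- Elimination is monotone in a: widening the band never un-eliminates.
- For five independent Gaussian analytes at a = 1 the eliminated fraction is
  ≈ 0.683⁵ ≈ 0.15, *not* 0.68 — the multi-dimensional rule is far more
  conservative than a per-analyte filter.
- a = 0 eliminates only records sitting exactly at every column mean.

### Self-weighting

For a retained record, each analyte's normalized value x maps to a signed
percentage with band half-width β = a·σ and side-specific extreme
deviations D⁺ = max − m, D⁻ = m − min:

    weight = 0                                          if |x − m| ≤ β
    weight = 100 · sign(x − m) · (|x − m| − β)/(D± − β) otherwise

The map is 0 across the whole normal band, piecewise linear beyond it, and
hits exactly −100 at the observed column minimum and +100 at the maximum
("worst-case low" / "worst-case high"). When the statistics come from the
scored data itself, an out-of-band value forces the observed extreme past
the band, so D± > β always holds; with externally supplied statistics
(training bands applied to new data) the scale can degenerate and the
operation raises rather than emitting unbounded weights.

The record's scalar label is the weight of maximal absolute value — a
subject's risk is taken to be driven by their most abnormal analyte. Exact
magnitude ties break by fixed analyte priority HTC > HGB > WBC > PLT > MPV.
This 5→1 reduction is a design choice of this package: it is deterministic,
keeps the label inside [−100, 100], and never lets a mild second analyte
dilute a severe first one. An alternative (e.g. signed max + mean blend)
would change bin populations but nothing structural.

### Interval selection and splitting

Labels are binned into signed 10 %-wide intervals — (k−10, k] for positive
k and [−k, −k+10) for negative — so every nonzero label falls in exactly
one bin (a retained record cannot have label 0). Each (interval, sign) cell
contributes min(existing, i_t) records, ranked by |label| descending with
ties broken by source row index; i_t defaults to 300. Ranking by extremity
is deterministic and favours the most informative (most abnormal) cases.

The train/test split is stratified per bin at fraction 0.75 (the evaluation
default; the fraction is a free parameter), with each bin's permutation
drawn from a generator seeded by (run seed, bin id) — so the split is
reproducible and insensitive to row order.

### Basis model

The predictor is ŷ = wᵀb(x) with b the 35-column expansion of the five
normalized analytes through seven maps: 1, |x|^1/2, |x|^1, |x|^1.2, |x|^2,
|x|^3, |x|^4, in analyte-major column order. Absolute values keep the
fractional powers real for held-out values below 0 on the training scale;
for in-range data (x ∈ [0,1]) they change nothing. Each analyte block
carries its own constant column, so bᵀb is rank-deficient by construction
(rank ≤ 31); every solver in the package tolerates this. Labels are scaled
from percent to [−1, 1] before fitting and back for reporting, which keeps
the optimization well conditioned.

### Learners

- **BLS.** The normal-equation solution is not unique here, so the batch
  solver returns the minimum-norm least-squares solution (`numpy.linalg.lstsq`,
  pseudo-inverse semantics). Residuals are orthogonal to the basis columns
  regardless of rank.
- **INN.** Per-sample descent w ← w + η·e_k·b_k from w₀ = 0, default one
  epoch at η = 0.05, samples visited in label-ascending order. The ordering
  is deliberate: it exposes the method's recency bias — late near-normal
  samples overwrite what early extreme ones taught it, which is the known
  failure mode of per-sample updates on sorted data. Stability requires
  η < 2/λ_max(bᵀb) samplewise; trajectories whose norm exceeds 10⁶ are
  flagged non-converged rather than raising. Whether to run one pass or to
  convergence is an open protocol choice; one pass is the default and
  `epochs` is exposed.
- **LSLC.** Per-sample update w ← w + η_c·b_k·y_k/(b_kᵀb_k + λ_k) with the
  closed-form multiplier λ_k = max(0, ‖b_k y_k‖₂/(p‖α‖₂) − b_kᵀb_k),
  followed by an explicit projection onto the feasible ball
  ‖w‖₂ ≤ p‖α‖₂ — the raw update alone does not guarantee feasibility at
  every iteration, the projection does. Defaults α = 1-vector, p = 10, a
  ball that comfortably contains the batch solution on unit-scaled labels.
  Note the update is driven by y_k, not the residual; it accumulates rather
  than corrects, and its error metrics are accordingly poor. It is kept in
  this form because that is the update rule the method defines; the error
  reports make the consequence visible instead of silently repairing it.
- **SCE.** Standard shuffled complex evolution: sample n·A points uniformly
  in a box (default [−10, 10] per parameter), rank by objective, stripe by
  rank into A complexes, evolve each complex β times by q-point subcomplex
  simplex steps (reflect the worst point through the centroid; if that
  fails, contract halfway; if that fails, resample uniformly), with
  subcomplices drawn by triangular rank weighting, α evolutions per
  subcomplex; reshuffle and repeat for Ω iterations or until the best
  objective reaches f_q. Defaults n=10, A=4, q=5, α=3, β=5, Ω=100, f_q=0.
  Non-finite objective values cause the point to be resampled inside the
  box. Fully deterministic per seed.

### Evaluation

"Mean error" is the mean absolute residual on unit-scaled labels; the
spread is the population standard deviation of the residuals. A signed-mean
variant is available behind `metric="signed"` for bias diagnostics. Reports
cover all four learners on both partitions; a learner that raises is
flagged with NaN cells without suppressing the others.

## Synthetic data

The generator emulates the structure of a large single-site screening
population: ~8.6 % female; ages drawn from four bins (18–40, 41–50, 51–64,
65–90) with screening-population weights; analytes drawn from Gaussians at
standard adult CBC reference values (HTC 42 ± 3.5 %, HGB 14 ± 1.3 g/dL,
WBC 7 ± 1.7 ×10⁹/L, PLT 250 ± 60 ×10⁹/L, MPV 10 ± 0.9 fL), so PLT dominates
the raw magnitude scale; 45 % of records are "abnormal", with 1–2 analytes
redrawn from a tail component shifted low (85 % of draws) or high (15 %).
Analytes are independent by default — consistent with the near-zero
cross-analyte correlations such panels show — with an optional correlation
knob for stress tests. Values are clipped at 0 (lab values cannot be
negative). Everything is deterministic per seed.

What the generator does *not* emulate: real measurement error structure,
age/gender-conditional analyte shifts, within-subject repeat correlation,
missing data, and the extreme scarcity of high-side abnormalities some real
screening tables show (in this generator, records near the high band edge
populate the positive bins more generously than a strongly low-skewed
clinical table would). Passing tests therefore demonstrate the pipeline's
mechanics and its statistical behaviour under a realistic-but-idealized
population, not clinical validity on any particular laboratory's data. The
test that examines degradation under positive-label scarcity constructs
that scarcity explicitly (thinning positive records to tens per bin) rather
than relying on generator defaults.

## Numerical choices and degenerate inputs

- Population (÷N) standard deviation everywhere, for internal consistency.
- Constant analyte columns make min-max normalization and correlation
  undefined; both raise a degenerate-input error naming the column.
- Band-edge values (|x − m| = β exactly) weight to 0; bin edges are
  half-open so no label lands in two bins.
- Selection ties (equal |label|) break by source row index; label-sort ties
  in INN's ordering are stable.
- All stochastic stages (generation, splitting, SCE) take explicit seeds;
  the pipeline derives per-stage sub-seeds from the run seed and logs them
  in the manifest, which is byte-identical across repeated runs.

## Problem sizes

The shipped tests and the acceptance script run on synthetic panels of
500–20,000 records — large enough that every bin of the selection table is
exercised and binomial checks (e.g. the female share, the Gaussian
elimination mass) have power, and small enough to run comfortably on one
CPU. The learner-level checks use reduced full-rank designs (20×6) where
convergence theory gives exact expectations.

## Known limitations

- The self-weighting map and the 5→1 label rule are this package's
  reconstructions of the general scheme ("0 in the band, ±100 at the
  observed extremes"); other monotone maps satisfy the same endpoints.
- LSLC as defined does not minimize prediction error (see above); treat its
  error metrics as a property of the method, not a bug in the fit.
- The data-driven bands are population-relative: on a panel of mostly sick
  subjects the "normal band" is not clinically normal.
- No missing-data handling: records must be complete.
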