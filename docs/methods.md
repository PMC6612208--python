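# Methods

## Model and procedure

The package implements a two-track assessment of competing health
technologies.

**AHP track.** The decision is a goal → criteria → sub-criteria →
alternatives hierarchy. For each sibling set, experts provide pairwise
importance ratios on Saaty's fundamental scale (1 = equal … 9 = extreme;
the mirrored comparison takes the exact reciprocal; intermediate grades 2,
4, 6, 8 and decimal grades 1.1–1.9 are accepted as inputs but never
produced by rounding). Group aggregation uses the weighted geometric mean
Π aₖ^βₖ, computed in the log domain; with equal credibility βₖ = 1/N this
is the N-th root of the product. The geometric mean is the only standard
pooling rule that commutes with reciprocity, so the group matrix is
reciprocal by construction. Aggregates are rounded to the nearest Saaty
integer on the ≥ 1 side of each pair and mirrored exactly (rounding both
orientations independently would break reciprocity); half-way values
round up by default (configurable), and a no-rounding mode retains the
raw geometric means.

Priorities come from the eigenvalue method: the principal right
eigenvector of the comparison matrix, which exists positive and simple by
Perron–Frobenius. The raw vector is reported at unit Euclidean norm and
the working weights at unit sum. Consistency is screened with
CI = (λmax − n)/(n − 1) and CR = CI/RI(n), using Saaty's random indices
(0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45 for n = 3…9; CR ≡ 0 for
n ≤ 2, where reciprocal matrices are always consistent). CR > 0.1 warns
and annotates rather than aborting — mildly inconsistent panels are
routinely retained in practice — and a strict mode raises instead.

Local weights propagate multiplicatively (global leaf weight = local ×
parent), which conserves mass: leaf globals sum to 1. Alternatives are
scored per leaf by operational indicator models — window sums (executed
exams, faults, refusals, profit), window-aggregate ratios (procedural
complexity, effectiveness, ROS = net operating margin / net revenues,
investment / purchase cost), and expert score sums (five safety
variables and six legal variables, each 1–10, legal with 1 best). Each
indicator carries an orientation; cost-type values (faults, procedural
complexity, side effects, ethical refusals, legal scores) are inverted by
reciprocal (epsilon floor 1e-9) before normalization — the standard AHP
treatment; a max-minus-value mode is provided. The default aggregates the
whole observation window first and normalizes once, since the indicator
definitions are window sums; a per-timestep-normalization variant is
available. Final alternative priorities are the sums of leaf
contributions (global leaf weight × local alternative weight), ranked
descending; totals are deliberately **not** renormalized — when the
contribution lists are supplied externally (as in the built-in case
study, whose published lists total ≈ 1.11) renormalization would hide
that fact, so a unit-sum flag and an optional normalized view are
reported instead.

**Likert track.** Questionnaire items are scored on an ordered agreement
scale (default 5 points; configurable 2–9 for reuse, with 4–7 typical).
Reverse-coded items map strong agreement to 1, giving the involution
reverse = (k+1) − direct on a k-point scale. Summaries report per-item
category frequency percentages, the mean, the per-item respondent count
(missing answers are excluded item-wise), and the satisfaction index
(mean − 1)/(k − 1) ∈ [0, 1].

**Gap analysis.** Sub-criteria are ranked by global AHP weight (the
"hierarchy of needs") with stable config-order tie-breaking. Importance
and satisfaction are then crossed: quadrants are cut at the per-axis
medians by default (the qualitative notions "high"/"low" are not
standardized, so the cutoffs are explicit, configurable, and echoed in
the output), and the improvement priority score is
importance × (1 − satisfaction) — monotone increasing in importance,
decreasing in satisfaction. Items in the high-importance/low-satisfaction
quadrant are flagged for improvement. Where several questionnaire items
probe one sub-criterion their indices are averaged; sub-criteria not
covered by any item are simply absent from the gap table.

## The built-in case study

The packaged worked example is the assessment of two fibre-optic
thyroglobulin biosensors (LOF, LPG) against cytological analysis, judged
by 80 experts: five criteria, fourteen sub-criterion leaves, three
alternatives. Its group comparison matrices, questionnaire codebook, and
per-alternative contribution lists ship in `ahpgap.case_study`. Two notes
on fidelity to the published tables: (a) the cytological-analysis
contribution list's published total (0.334414) disagrees with the sum of
its own published summands (0.3430); the package always sums summands, so
the cytology total reported here is 0.3430 — the ranking is unaffected.
(b) The leaf-by-leaf attribution of the contribution lists was not
published, so `synthesize_priorities` takes contribution lists as
explicit inputs rather than pretending to know the mapping.

## Synthetic data generator

`ahpgap.simulate` emulates a complete study with known ground truth.
Judgments: respondent k's ratio for pair (i, j) is
round_to_saaty(clip((wᵢ/wⱼ)·e^ε, 1/9, 9)) with ε ~ N(0, noise²) —
multiplicative log-normal noise respects the ratio scale and perturbs
reciprocally-consistently. Likert answers: a draw from N(mean,
dispersion) clipped to the scale and rounded, then emitted as the
category a respondent with that satisfaction would tick (so reverse-coded
items arrive on the agreement scale and exercise the downstream coding).
Operational series: Poisson arrivals with binomial thinning, so internal
constraints (effective ≤ executed ≤ incoming) hold by construction;
financial fields derive linearly from executed counts. All generators are
pure functions of (scenario, seed) via `numpy.random.default_rng`.

The frozen default scenario mirrors the case-study conditions: the
case-study weight vectors as ground truth at every node, N = 80
respondents, judgment noise 0.3 (a moderate inconsistency level that
keeps group CR well under 0.1), Likert dispersion 0.8 with item means
following the published satisfaction pattern (high for safety, staffing,
side effects, social respect; low for clinical efficiency, effectiveness,
cost), and operational rates under which LPG modestly outperforms LOF,
which outperforms cytology.

What the generator does **not** emulate: correlated judgments across
pairs within a respondent (real experts are coherent beyond chance),
item non-response patterns, acquiescence or central-tendency response
styles, and day-of-week or trend structure in the operational series.
Passing tests therefore demonstrate correctness of the computational
pipeline under idealized sampling, not robustness to real survey
pathologies.

## Numerical choices and known limits

- Eigen analysis uses the dense solver, with a power-iteration fallback
  (tolerance 1e-10, cap 10 000 iterations) should the dense eigenvector
  come out with mixed signs; matrices here are ≤ 9×9, so cost is nil.
- Ratios parse as exact `fractions.Fraction`s ("1/7"), and matrix CSVs
  emit exact fractions where possible, so reciprocity survives text
  round-trips to 1e-12; readers accept both "." and "," decimal marks,
  writers emit "." only.
- Reciprocity/diagonal validation tolerance is 1e-9; weight unit-sum
  tolerance 1e-9.
- Saaty rounding imposes a deterministic floor on parameter recovery:
  with the case-study truth, the economic-vs-technical true ratio ≈ 12.2
  clamps to 9, and rounding shifts other entries, so even a noiseless
  survey recovers criteria weights only to ≈ 0.03–0.04 per component.
  Recovery is therefore tested exactly against the rounded-truth
  construction, and noisy-recovery tolerances (L1 < 0.08 at noise 0.3,
  N = 80, rounded aggregation) were frozen from a 100-replicate pilot.
  The rounding floor also means the L1-vs-N improvement is cleanest when
  aggregation keeps raw geometric means.
- Tie-breaking is everywhere stable in config order (rankings, quadrant
  ranks, hierarchy of needs), making printed tables bit-reproducible.
- Test and acceptance problem sizes (80 respondents, 50-day windows,
  30–100 replicates) run in seconds on one core; they are the package's
  default study scale, chosen to match the case-study survey size.
- Missing judgments drop the respondent for that pair and renormalize the
  credibility weights over those present — a pragmatic default for
  near-complete questionnaires; it is not a principled imputation, and
  heavily incomplete surveys deserve an explicit design instead.
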