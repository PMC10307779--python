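# Methods

## Study model

The pipeline analyses a five-phase within-subject behavioral study of rats
(n = 15 by default, reduced samples supported throughout):

1. **Reflex pain testing** (days 6–9): per session, two or more radiant-heat
   withdrawal latencies per hindpaw, each forced into the apparatus window
   [5, 20] s (20 s cutoff protects tissue; 5 s is the minimum accepted
   response).  The per-paw latency is the mean of the two numerically
   closest trials; the session latency is the mean of the two paws.
2. **Conditioning** (days 13–16): each day one vehicle (VEH) and one
   oxycodone (OXY, 0.56 mg/kg i.p.) session in assigned compartments of a
   three-compartment place-preference box; locomotion recorded as beam-break
   counts.
3. **CPP and extinction tests** (pre-test day 10; tests on days 17, 24, 28,
   38, 45, 49, 51): 1200 s of free exploration; time in the OXY-paired,
   VEH-paired and center compartments recorded.
4. **Sham/CCI surgery** (≈ day 56), balanced assignment.
5. **Post-surgery testing**: three reflex sessions (days 63–65) and a final
   place test (day 66).

## Outcome measures

Eight pre-surgery and six post-surgery measures are derived per animal
(`ethopharm.measures`); all slope measures are ordinary least squares.
Sign conventions: reflex-pain change, locomotor habituation and CPP
extinction are *inverted* slopes (decline → positive); behavioral
sensitization is uninverted (rise → positive).  Abscissae are session
index (1–4) for the reflex and conditioning slopes, whose units are per
session, and calendar day for the extinction slope, whose unit is s/day
and whose tests are unevenly spaced.  Whether the extinction regression
treats day 17 as x = 17 or re-zeroes to 0 only shifts the intercept; the
slope — the measure — is identical either way.

The locomotor-habituation column is the one transform-bearing measure: the
raw inverted slopes are Shapiro–Wilk-tested across the cohort, and if
p < 0.05 a signed square root (sign(s)·√|s|, the monotone extension of the
square root to negative slopes) is applied to every animal and recorded in
a transform flag.  All-or-none application keeps the column on one scale;
the flag lets a consumer undo it.

Two tie/edge rules the measure definitions leave open are fixed
deterministically: the two-closest-trial rule breaks gap ties by the
earliest pair in acquisition order, and the closest pair is searched
globally among however many trials were taken.  CPP scoring defaults to
pre-test subtraction (time in the OXY-paired compartment minus its
pre-test value); VEH-subtraction and proportion-of-time scorings are
implemented as alternatives because the choice of scoring can change
end-of-extinction conclusions.

Missing phases yield missing measure values for that phase only — no
imputation.  Measures are carried at full precision; report layers round.

The dose translation uses the body-surface-area rule
(dose ÷ 6.2) × 70 kg for the rat → human conversion, reported to one
decimal (0.56 mg/kg → 6.3 mg).

## Statistical battery

`ethopharm.stats` returns (statistic, df, two-tailed p) for: one-sample,
paired and pooled-variance (Student) unpaired t tests; a within-subjects
one-way ANOVA partitioning SS into subjects/treatment/error with
uncorrected df (k−1, (k−1)(n−1)) and no sphericity correction;
Shapiro–Wilk (Royston approximation via scipy); Pearson r with p from
t = r√(n−2)/√(1−r²); and Mann–Whitney U summarised by a tie-corrected
normal-approximation Z with no continuity correction,
p = 2(1 − Φ(|Z|)).  All p values are two-tailed and uncorrected.  The
pooled-variance and uncorrected-df conventions are deliberate: they match
the integer degrees of freedom this literature reports (t with df
n₁+n₂−2; F with df 3,42).  Zero-variance samples whose mean equals the
null value return the exact null (statistic 0, p = 1); zero variance off
the null raises, since the statistic is undefined.  Small implementation
differences between Shapiro–Wilk variants (±0.005 in W on borderline
samples) are expected and immaterial to the transform trigger.

The report battery compares sham vs CCI per post-surgery measure with the
parametric test unless either group fails a Shapiro–Wilk check at
p < 0.05, in which case it switches to Mann–Whitney.  This codifies as a
policy what is otherwise decided case by case.

## Data reduction

`ethopharm.cluster` composes: pairwise-complete Pearson correlation (the
per-pair n — which differs once post-surgery attrition removes animals —
feeds the p transform), the sign-blind distance d = 1 − |r|, classical
(Torgerson) MDS, and k-means.

* **AOE ordering**: measures are displayed sorted by the angle
  atan2(e₂ᵢ, e₁ᵢ) of the two leading eigenvectors of r.  Each eigenvector
  is sign-flipped if its entry sum is negative, making the order
  deterministic; a fully diagonal matrix has a degenerate leading
  eigenspace and keeps input order.
* **Classical MDS**: B = −½ J D² J; coordinates are √λ·v for the leading
  positive eigenvalues; per-axis sign is fixed so the largest-magnitude
  coordinate is positive.  1 − |r| is generally non-Euclidean, so negative
  eigenvalues are dropped and the maximum reconstruction error is always
  reported on the result object rather than hidden.
* **k-means**: Lloyd's algorithm on the 2-D MDS coordinates (clustering is
  applied to the scaling output, not the raw distance matrix), with greedy
  spread-out seeding (random first center, then repeatedly the point
  farthest from the chosen set), best of 10 restarts by within-cluster sum
  of squares, a per-iteration monotone-descent assertion, and labels
  canonicalised by first appearance.  Deterministic for a fixed seed.
* **Cluster-count vote**: for each k in the search range (2–6 pre-surgery,
  2–4 combined) four internal validity indices score the k-means solution —
  mean silhouette (max), Calinski–Harabasz (max), Davies–Bouldin (min),
  Dunn (max) — and each votes for its best k; majority wins, ties to the
  smallest k.  This replaces a 30-index consensus library with a
  documented four-index vote spanning both index families; only the
  winning k is ever consumed downstream.

## Synthetic cohorts

Each animal carries eight latent traits (basal latency, latency decline,
basal locomotion, habituation, acute OXY boost, sensitization slope, CPP
strength, extinction rate), drawn from a multivariate normal with a
configurable correlation matrix via its symmetric PSD square root.  Traits
map *linearly* to session observables, so the derivation pipeline is the
generator's inverse wherever no bound binds:

* reflex trials: basal − decline·(session−1) + N(0, σ_trial), clipped to
  [5, 20] per trial (clipping precedes trial averaging, mirroring the
  apparatus cutoff acting on each trial);
* VEH counts: mean basal_loco − habituation²·(session−1) — the habituation
  trait is planted on the square-root scale so the downstream transform
  recovers it exactly; OXY counts: same-day VEH mean + boost +
  sensitization·(session−1).  Counts are negative-binomial with variance
  μ + d·μ² (integers); at d = 0 the generator emits the deterministic mean
  so that noiseless cohorts are exactly linear (a Poisson limit would
  never vanish and would make exact round-trip recovery impossible);
* place tests: OXY time = pre-test time + CPP strength −
  extinction·(day − 17) + N(0, σ_cpp); center time drifts upward per test
  (the empirical creep into the neutral compartment); VEH time is the
  remainder; the triple is clipped at 0 and rescaled to the 1200 s total;
* surgery: balanced sham/CCI; CCI subtracts a configurable latency effect
  from the surgeried (right) paw only and shifts the day-66 OXY time; the
  day-66 trajectory otherwise plateaus at the day-51 value (extinction is
  treated as complete rather than extrapolated without bound).

One global seed drives a per-animal, per-phase `SeedSequence` split, so
enlarging a cohort never changes existing animals' records.

**Default (study-condition) parameters** anchor to the printed group
values: trait means 18.7 s, 2/3 s/session, 675.3 counts, 8.7 √counts/
session, 441.7 counts, 104.0 counts/session, 100 s, 4.4 s/day; trait SDs
are the printed SEMs × √15 (CPP strength's SD is backed out of its
t statistic); pre-test OXY time 393.4 ± 92.2 s with the center at 413.2 s
(both outer compartments unbiased at ~393 s of the 1200 s test).  The
planted correlations are the two headline associations: basal latency vs
sensitization −0.7 and basal locomotion vs habituation +0.6.  Measurement
noise defaults — 0.4 s per reflex trial, count dispersion 0.002, 15 s per
place test — are set so between-animal variance dominates within-animal
noise, consistent with assays designed as reliable individual-difference
phenotypes.  CCI reduces surgeried-paw latency by 8 s and shifts day-66
OXY time by −60 s by default (a strong nociceptive effect, no
reinstatement).

**Validation regime.** Under the study-condition defaults the 20 s cutoff
sits ~1.4 SD above the mean basal latency and low-locomotion animals
approach the zero-count floor, so censoring — not the pipeline — limits
round-trip recovery there.  `validation_config()` therefore places traits
in the interior of every dynamic range (basal latency 15 ± 1.5 s,
locomotion 1500 ± 200 counts, OXY baseline high enough that the day-4
OXY mean stays ~4 SD above zero, extinction rate 3 ± 2 s/day so the
OXY-time trajectory never overflows the 1200 s budget) with reduced count
dispersion (2e−4).  In this regime a noiseless cohort round-trips every
planted trait to ~1e−13, and across noisy cohorts at n = 200 the mean
derived-measure correlation matrix deviates from the planted latent
matrix by < 0.05 elementwise.  The residual deviation is dominated by two
real, understood couplings: shared day-13 count noise (which links basal
locomotion, acute OXY locomotion and the two conditioning slopes) and the
shared day-17 test (which links CPP magnitude to the extinction slope).

**Planted structures.**  `three_block_config()` plants the three-cluster
membership of the pre-surgery panel ({basal reflex pain, sensitization,
extinction — latency entering negatively}, {locomotion, habituation,
acute OXY, latency change}, {CPP magnitude}) at |ρ| = 0.8 within blocks.
For the combined 14-measure panel, `four_block_measure_frame()` draws the
measure table directly from a four-block MVN whose between-block
correlations are 1 − distance between planted *planar* blob centers:
because 1 − |r| caps distances at 1, four mutually equidistant blocks are
tetrahedral and cannot embed in two dimensions, so a fixture with planar
geometry is the correct way to validate 2-D-MDS-based cluster-count
selection.

**What passing tests do and do not show.**  The generator emulates linear
trait-to-behavior maps with Gaussian traits, negative-binomial counts and
compositional place tests.  It does not emulate within-session time
courses, sex effects (the study pooled sexes), pharmacokinetics,
non-linear floor/ceiling psychophysics beyond hard clipping, or
surgical attrition.  Recovery results therefore certify the *pipeline*
(derivations, statistics, clustering), not any claim about real rat data;
with real data near the 20 s cutoff, derived correlations will be
attenuated relative to the latent ones, which is worth remembering when
interpreting small-sample correlation matrices of censored measures.

## Problem sizes and numerics

Validation runs use n = 200 animals and 25–100 seeds (chosen to make
Monte-Carlo error small relative to the 0.05 recovery band); the planted
default cohort is n = 15.  OLS is computed by centered sums; the PSD check
tolerates eigenvalues ≥ −1e−8; MDS drops eigenvalues below 1e−10 of the
spectral radius; k-means declares convergence on label fixpoints with a
1e−9 monotonicity tolerance; compositional validation of place tests uses
a 1e−6 s tolerance.  p values from rounded printed r values are
reproducible to ~2e−3, the precision 3-decimal rounding of r permits.
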