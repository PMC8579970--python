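# Methods

This note documents the models, conventions and numerical choices in
`soursentinel`, and what the synthetic experiments do and do not show
about real data.

## Data model and time

All analysis operates on six flat tables joined into an
`ExperimentBundle` (counts, taxon annotations, sample metadata,
sulfide, treatment schedule, cell counts). Time is stored as integer
day offsets from experiment start; calendar dates in input files are
converted on load using the earliest date in the bundle as day 0 —
arithmetic on offsets is unambiguous, and ragged per-column sampling
grids are accepted throughout. Counts may be fractional after 16S
copy-number correction; a flag on the count table records whether
correction has been applied, and applying it twice is an error rather
than a silent bias.

## Phase segmentation

Phases are assigned per column by a four-state rule driven by the
sulfide series and the nitrate schedule: S before `nitrate_start`; TM
from `nitrate_start` while sulfide is strictly above the threshold
(default 1.0 mM, overridable per column); M from the first treated
time point with sulfide at or below the threshold; R from
`nitrate_stop`. Two deliberate choices:

* **M is sticky.** A sulfide blip above the threshold after M has been
  entered does not revert the column to TM, keeping TM a single
  contiguous window, which is how transition windows are reported in
  practice.
* **Strict comparison.** A value exactly at the threshold ends TM
  ("above" means strictly above).

Missing sulfide at a metadata time point is filled by carrying the
last observation forward; a time point before the first observation is
an error. Note the threshold monotonicity: a decaying sulfide series
crosses a *higher* threshold *earlier*, so raising `threshold_mm` can
only shorten (never lengthen) the TM phase; the property suite asserts
exactly this direction.

## Indicator statistics

* **Anomaly** of a signal x at time t is (x_t − m)/m, where m is the
  mean of x over the *averaging window* — all effluent time points of
  the column, whatever phases its observed lifetime spans (sessile
  samples are never part of the window). The anomalies over the window
  sum to zero identically; this is asserted for every emitted series.
* **Critical time points** are TM-phase time points whose SSP relative
  abundance strictly exceeds the TM-phase mean. Ties are not critical
  (conservative reading of "higher than the average").
* **SSP selection** ranks SRB-flagged genomes by TM-phase mean
  relative abundance, descending, ties broken lexicographically. The
  full ranked list is reported (filtered by a configurable floor,
  default 0), not a single hard call — columns can host two
  co-dispersing SRB populations, and the report should show both.
* **Absolute abundance** is rel% / 100 × total cells/ml. Tukey
  outliers (linear-interpolation quartiles at positions 1 + (n−1)q,
  fences Q1 − 1.5·IQR and Q3 + 1.5·IQR) are removed from the total
  cell counts per column *per phase group* before the product is
  taken; groups with fewer than four observations cannot anchor fences
  and pass unfiltered with a warning. Critical time points form their
  own "CT" group next to S/TM/M/R, and a Kruskal-Wallis test across
  the groups is reported descriptively — no pipeline decision gates on
  a p-value.

## Diversity conventions

Shannon entropy is computed in nats and Simpson's index as the
Gini-Simpson form 1 − Σp² (both configurable via flags: `base` for
Shannon, `form="dominance"` for Σp²), matching the conventions of the
ecology packages this analysis style comes from. Bray-Curtis
dissimilarity is 1 − 2Σmin(a,b)/(Σa+Σb) (delegated to scipy), PCoA is
classical metric scaling (delegated to scikit-bio, with degenerate
all-zero matrices handled and axes trimmed to positive eigenvalues).
Ordination runs on relative abundances (%) of copy-number-corrected
sequence variants. Rank tests use scipy: the two-sided Mann-Whitney U
with the exact permutation null when the pooled sample has at most 10
tie-free observations, the tie-corrected asymptotic form otherwise;
Kruskal-Wallis with tie correction.

## DSR pathway trend

The community relative abundance of the dissimilatory sulfate
reduction pathway is the sum of genome-level relative abundances over
genomes flagged `has_dsr` — binary pathway presence, normalized to the
whole community (not to total pathway counts; the binary community
normalization is the minimal reading of a predicted-pathway relative
abundance, and the choice is isolated in one function). The
cross-column average anomaly is an unweighted per-time mean and SD
(ddof 1; SD 0 for a single column), omitting columns unobserved at a
time point and reporting the contributing count.

### Trend smoother

The trend is a penalized cubic B-spline regression (basis dimension
min(10, max(n/4, 4)), knots at quantiles of the observed times) with
an exact curvature penalty ∫(f″)² computed by two-point Gauss-Legendre
quadrature per knot interval — B″ is piecewise linear for cubic
splines, so the quadrature is exact and polynomials up to degree 1 are
unpenalized and reproduced exactly. The penalty weight is selected by
generalized cross-validation over a 29-point log grid (10⁻⁶..10⁸);
among fits whose GCV scores are numerically indistinguishable the
smoothest is preferred, which makes noiseless (exact-fit) inputs
well-behaved. The ± 2 SE band uses the hat matrix and a residual
variance estimate with n − edf denominators. The smoother is
cross-checked against a statsmodels penalized-spline GAM on noisy data
in the test suite; it exists as first-class code because the smoother
must also handle degenerate exact-fit inputs cleanly.

## Synthetic experiment generator

The generator emulates the study design the package is built around:
20 up-flow columns (10 nitrate-treated), a 148-day timeline sampled
every 2 days, nitrate from day 44 to day 120, three sessile sections
per column harvested at one of four sacrifice days (68/72/112/148; the
last nontreated column is never harvested, giving 19 × 3 = 57 sessile
samples), multinomial read sampling at mean depth 40,709 (SD 10,527,
truncated at 1,000), and dispersal pulses 2 and 4 days after nitrate
initiation.

Mechanics, per column (all driven by a per-column RNG substream
derived from the global seed, so single columns are reproducible):

* **Sulfide**: saturating rise toward a 2.5 mM plateau (τ = 8 d);
  for treated columns an exponential decay from the treatment start
  whose rate is fixed so the 1 mM threshold is crossed
  `mitigation_lag_days` (default 5) later — guaranteeing a TM phase
  of at least two sampling intervals — then a rebound toward the
  plateau (τ = 10 d) after withdrawal. Measured values carry 5%
  lognormal noise; the latent community is driven by the noiseless
  curve (assay noise should not move the community).
* **Community**: three guilds. The SRB guild fraction tracks the
  normalized sulfide level between 0.15 (full sulfidogenesis) and 0.02
  (mitigated); within-guild shares are Dirichlet with elevated weight
  on the three named indicator genomes (the field observation being
  emulated is that the indicator SSPs are among the most abundant
  SRBs). A nitrate-responder guild blooms from 0.02 to 0.30 under
  treatment (τ = 4 d) and relaxes after withdrawal. The Dirichlet
  background takes the remainder. Per-genome lognormal jitter
  (sd 0.10) models day-to-day community noise and keeps the
  post-amendment window of nontreated columns statistically
  exchangeable — which is what makes the nontreated peak-time
  uniformity test meaningful.
* **Dispersal injection**: the sessile composition (70% SRB, with the
  designated SSP at 70% of the guild) is mixed additively into the
  effluent composition at the dispersal days, with the weight solved
  exactly so the SSP's latent fraction equals `dispersal_fold` × its
  baseline TM-phase mean fraction. Under the defaults the target is
  always below the sessile SSP fraction, so the mixing weight stays in
  (0, 1); an infeasible target is clamped to the pure sessile signal
  with a warning. `dispersal_fold = 1` skips the injection entirely
  (negative-control mode).
* **Sequencing**: per-variant read probabilities are proportional to
  latent genome fraction × variant weight × 16S copy number, so the
  copy-number correction in the pipeline recovers cell fractions
  consistently.
* **Cell counts**: lognormal (μ_log 16.1 ≈ 10⁷ cells/ml, σ_log 0.4)
  with probability 0.02 of replacement by a ×30 or ÷30 outlier —
  exercising the Tukey filter.

**What passing tests show — and what they do not.** The generator
provides known truth for every stage, so the suite demonstrates that
the pipeline recovers injected dispersal days with high sensitivity,
identifies the designated SSP, and reproduces the expected
absolute-abundance and DSR-anomaly patterns *under the modeled
conditions*: well-mixed guild dynamics, lognormal noise, binary
pathway annotations, and a single dispersal mechanism. Real effluent
data add unmodeled structure — chimeras and sequencing error,
archaeal community members (deliberately out of scope), non-lognormal
count noise, drifting baselines, and annotation error in copy numbers
and pathway calls — so performance numbers from the synthetic design
are upper bounds, not field estimates.

## Scaling of the shipped experiments

The default design (20 columns, ~1,100 samples) runs in well under a
second per experiment, so the recovery experiments in the test suite
and the acceptance script use 10–20 independent seeds of the full
design; the chi-square uniformity check uses 50 seeds of a reduced
all-control design (4 columns, 80 days) where only the nontreated
dynamics matter.

## Known limitations

* The SSP selection rule (TM-mean ranking) is a reconstruction of an
  informally described choice; the ranked-list report exists precisely
  so users can see the competing candidates.
* Whether the DSR "relative abundance" should be normalized to total
  pathways rather than the community is genuinely open; the
  community-normalized form is implemented and the alternative would
  slot into `dsr_relative_abundance` without touching the anomaly
  machinery.
* Sessile community enrichment is a free parameter
  (`sessile_srb_fraction`, `sessile_ssp_share`), not a calibrated
  value — quantitative sessile composition is rarely measured.
* Bacteria only; no rarefaction; no constrained ordination (CAP); no
  sequence-level simulation.
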