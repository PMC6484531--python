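# Methods

## Data model and normalization

The unit of input is a per-cell feature table: one row per segmented cell
with `plate`, `well`, `treatment` (the negative control is `"DMSO"` by
default), optionally `moa` and `concentration`, and numeric feature columns
("parameters").  Feature values must be finite or explicitly missing (NaN);
missing cell values are skipped by every statistic.

Two per-plate normalization schemes are provided, both referenced to the
plate's control population:

* **Linear percentile scaling** (cell level): with `p_lo`/`p_hi` the control
  1st/99th percentiles of a parameter on a plate, `x -> (x − p_lo)/(p_hi −
  p_lo)`.  No clipping is applied — the map is affine, so treated cells may
  legitimately land outside [0, 1].  Parameters whose control percentiles
  coincide on some plate carry no dynamic range there and are dropped from
  the whole table (keeping the table rectangular) with a warning.
* **Well-average z-normalization**: well means are standardized per plate
  against the control well means, using the sample (n−1) standard deviation
  — the control wells are a sample of control behavior, not the population.
  At least two control wells per plate are required.

Percentiles use linear interpolation between order statistics
(`numpy.percentile(..., method="linear")`) everywhere; the method is
configurable but shared across modules so edges and scaling agree.

Quantile binning itself is applied to *unnormalized* cell data: bin counts
are invariant under any strictly increasing per-plate transform of a
parameter (the edges transform with the data), so cell-level scaling before
binning is a no-op by construction and is not required.

Wells with fewer than 50 cells (configurable) are flagged at averaging and
excluded from the stability tests; a goodness-of-fit test on tiny wells has
expected bin counts too small for the chi-square approximation.

## Binning

Per plate × parameter, the pooled control values define k−1 interior cutoffs
at the `i·100/k`-th percentiles (k = 5 by default: the 20/40/60/80th).
Intervals are half-open `[e_{i−1}, e_i)` with the first bin open below and
the last closed above; a value exactly on a cutoff goes to the **upper** bin.
The convention is arbitrary but must be fixed: it only matters at ties, i.e.
for discrete parameters.

Discrete or near-constant parameters (e.g. nuclei count, nearly always 1)
produce duplicated cutoffs.  Interior bins with coinciding edges have zero
width, can hold no cells, and are *uninstantiated*; only instantiated bins
carry counts, percentages and z-scores.  Under the ties-to-upper rule the
concentrated mass of such a parameter lands in the top bin (with
ties-to-lower it would be the bottom bin — a mirror image with no downstream
consequence, since both extreme bins are always retained together).
Uninstantiated bins surface as missing features and are removed by the
fingerprint missing-column filter.

Per (well, parameter, bin) the output is the cell count, the percentage of
the well's non-missing cells, and

    z = (percent − mean_percent_DMSO) / sd_percent_DMSO

with mean/sd taken over the plate's control wells (sample sd).  Percentages,
not raw counts, enter the z-score so wells of different cell number are
comparable.  By construction the control wells' z-scores have mean 0 and
sample sd 1 per (parameter, bin); bins whose control sd is 0 are degenerate
and yield missing z.  Control pooling is per plate by default; pooling across
the screen is exposed as an option.

## Stability of parameters

Drawing a control well's cells into k equal-occupancy bins is sampling with
replacement from the pooled control urn, so the counts are multinomial with
expected occupancy uniform over the instantiated bins (renormalized — this
keeps discrete parameters with 2–4 instantiated bins testable; a parameter
with a single instantiated bin is untestable and treated as unstable).  Each
(control well, parameter) gets

    chi2 = sum_b (O_b − E_b)^2 / E_b,  E_b = n · p_b,  df = #bins − 1

with the upper-tail chi-square p-value, Bonferroni-adjusted with the family
equal to all tests computed on the same plate (the family is configurable to
screen-wide).  A well *passes* for a parameter when the adjusted p exceeds
0.05 (configurable); the parameter's stability fraction is the share of
passing wells among tested wells (untestable wells are excluded from the
denominator).

The threshold ladder retains, at each of the 20 thresholds 0.01, 0.06, …,
0.96 (step 0.05), the parameters whose fraction is at least the threshold,
giving nested fingerprints.  The operating threshold is chosen by
leave-one-out classification accuracy; ties break toward the larger threshold
(the sparser fingerprint).  The retained *sets* depend only on control wells
— relabeling or removing any treatment class leaves them bit-identical —
while the threshold *choice* uses the labeled profiles.

## L1 baseline

MoA labels are regressed on the fingerprint with L1-penalized logistic
regression over alpha ∈ {0.01, 0.05, 0.1, 0.5, 1, 2, 4, 6, 8, 10}, where
alpha multiplies the L1 term of the per-sample-averaged loss (equivalently
`C = 1/(alpha·n)` in the inverse-regularization convention).  Features are
standardized to zero mean / unit sd before fitting, intercepts are
unpenalized, the multiclass scheme is one-vs-rest (softmax available), and a
feature survives an alpha iff some class coefficient exceeds 1e−8 in
magnitude.  Solver tolerance 1e−6, at most 10⁴ iterations, fixed random
state.  The best alpha is chosen exactly like the stability threshold
(leave-one-out accuracy, ties to the sparser model).  Alphas that shrink
every coefficient to zero are skipped with a warning.

## Classification

Fingerprints are built per well (or per replicate median, grouped by compound
× concentration with the componentwise median) in three modes: `well_average`
(one feature per parameter), `all_bins` (one per parameter × bin z-score) and
`extreme_bins` (bins 1 and k only).  Columns containing any missing value are
dropped before distances are computed; control wells are excluded unless
requested.

Distances are cosine, `1 − u·v/(‖u‖‖v‖)`, on the features as produced
upstream (no further per-feature rescaling).  Leave-one-out nearest-neighbor
classification excludes, for each query, either only the query itself
(`self_only`) or every profile of the same compound (`same_compound`, the
default not-same-compound protocol for MoA benchmarks).  Exact distance ties
resolve to the lexicographically smallest profile id, making the report
independent of row order.  Queries left without candidates are reported as
unclassifiable and excluded from the accuracy denominator rather than
silently dropped.

The held-out-class experiment removes one MoA class, reruns the feature
selection (stability ladder or L1 scan) on the held-in profiles, applies the
winning feature set to the full profile set, classifies, and reports the
number of misclassified holdout profiles.  Because stability selection never
sees labels, its retained sets are unchanged by the holdout; L1 selection
drops features informative only for the missing class, which is precisely the
generalization gap the experiment measures.

## Synthetic screens

`generate_screen` emulates a plate-based screen on a latent standard-normal
scale per (plate, parameter), warped by a per-plate location and scale (and
optionally a log-normal transform, since real morphology features are skewed
— binning is invariant to the warp, which the tests exploit):

* *stable uninformative* parameters are i.i.d. baseline draws everywhere;
* *noisy* parameters add one `Normal(0, noise_drift_sd)` offset per well
  (default drift 0.5 baseline sds), in control and treated wells alike;
* *degenerate* parameters take a single constant for 99.5 % of cells;
* *informative* parameters are partitioned into disjoint per-class
  signatures (3 parameters per class by default); a treated well shifts each
  signature parameter by ±2 baseline sds, either translating the whole
  population or — for half the signature, the *bimodal split* — moving one
  half of the cells up and the other half down, which leaves the well mean
  nearly unchanged while loading the extreme bins.

Cell counts per well are Poisson around 500 (floored at 10) so the
percentage-based z machinery is exercised.  Default layout: 2 plates × (20
DMSO + 9 treated) wells, 100 parameters with 20 noisy and 2 degenerate, 3
classes × 3 compounds, each compound once per plate.  All randomness derives
from a single seed through per-(plate, well) child streams, so identical
seeds give byte-identical tables and any subset can be regenerated
independently.

What the generator does *not* emulate: correlation between parameters beyond
the class signatures, spatial plate effects (edge wells, gradients), dose
response, segmentation artifacts, or the heavy-tailed error structure of real
image features.  Passing tests therefore demonstrate the statistical
machinery (calibration, recovery, selection, generalization ordering) on
data matching the model's assumptions, not performance on any real screen.

`generate_worked_example` builds a tiny fixed screen (2 plates × 8 wells ×
100 cells × 6 parameters) whose `uniform` parameter is dealt so the pooled
control population is exactly 1..500 per plate, four control wells hold bin
counts (15, 18, 22, 22, 23) and a planted drift well holds (40, 28, 12, 12,
8) — hand-checkable: χ² = 736/20 = 36.8 and 46/20 = 2.3 on df 4.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at the default conditions above
(tens of wells, ~500 cells per well, 100 parameters); the held-out-class
comparison uses a reduced screen (2 plates × 10 DMSO wells, 200 cells/well,
30 parameters) per seed, which is ample for the qualitative ordering it
checks.  Other conventions: sample (n−1) standard deviations throughout;
ties at bin edges to the upper bin; Bonferroni family per plate;
zero-coefficient threshold 1e−8 on the standardized scale; cosine similarity
clipped to [−1, 1] before conversion to distance; accuracy ties in threshold
and alpha selection resolved toward the sparser fingerprint.

## Known limitations

* The chi-square test's power grows with cell count: at several thousand
  cells per well even tiny occupancy deviations reject, so the stability
  cutoff and thresholds must be tuned per dataset (the ladder exists for
  exactly this reason).
* Expected occupancy uniform over instantiated bins makes heavily discrete
  parameters fail the test by construction; they are removed as unstable
  rather than modeled.
* Replicate handling assumes a compound appears at most once per plate per
  concentration.
* The generator's per-class signatures are disjoint; overlapping signatures
  (shared phenotype axes) are not modeled.
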