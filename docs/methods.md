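# Methods

This note documents the model and procedure implemented by `cdrmobility`,
the parameters that matter, the numerical conventions, what the synthetic
generator does and does not emulate, and the design choices made where
the design was genuinely open.

## Data model

A study is a single calendar year (default 2013, 365 days) over a fixed
partition of `r` regions (the finest spatial unit observable in the
events, e.g. administrative arrondissements) grouped many-to-one into
`N_Z` analysis zones (e.g. livelihood zones). Event timestamps are
quantized to 10-minute ticks; a single timezone is assumed. Region
centroids are decimal-degree WGS-84 coordinates; point-to-point distances
use the haversine formula in km.

Time bins per resolution: daily 365 (366 in a leap year), weekly 53,
biweekly 24, monthly 12.

* Weekly bins are consecutive 7-day blocks anchored at January 1; the
  trailing 1-day block is its own bin (365 = 52·7 + 1). ISO weeks would
  straddle the year boundary and change the bin count.
* Biweekly bins split each calendar month at day 15 (days 1–15 and
  16–end). Fixed 14-day blocks would give 27 bins, not 24; two bins per
  month is the only partition consistent with 24.

## Trajectory regularization

The daily preferential region of user `p` on day `d` is the region with
the most event records that day (record counts, not distinct ticks). The
IT-Matrix cell is 0 (missing) when the user has no events that day.
Labels are 1-based; the missing sentinel shares the integer matrix.

**Ties** in every "most frequent" reduction (within a day, within an
aggregation window) go to the label observed earliest in time in that day
or window; if two labels first appear at the same 10-minute tick, the
smaller label wins. This is deterministic and independent of row or label
ordering. Two events at the same tick in different regions both count as
visits.

**Interpolation** fills each missing cell with the nearest previous
observed value in its row (last known position, across gaps of any
length); the leading missing run is back-filled with the first observed
value. Observed cells are never modified, so the operation is idempotent,
and afterwards every user is somewhere on every day — population counts
from an interpolated matrix conserve N column-wise. A user with no
observed day at all is an upstream-filtering error, not an interpolation
case. An optional `max_gap` cap stops forward-fill beyond a run length;
it is off by default because the stated regularization rule has no cap.

**Aggregation order.** Time aggregation is always computed from the daily
matrix (weekly, biweekly and monthly bins each take the mode over their
own days), never by stacking coarser intermediates, which would compound
tie artifacts. The canonical pipeline order is time regularization first,
then space aggregation; mapping regions to zones before or after the
per-window mode does not commute in general (a zone can win a window that
none of its member regions wins), and the package fixes and documents the
daily-first, region-first order.

## Population counts and signatures

`population_count` counts users per label per bin; missing cells count
nowhere. Signatures are z-scores with **population** standard deviation
(ddof = 0), so any non-constant series has exactly mean 0 and variance 1;
constant series map to all zeros rather than NaN.

`interpolation_bias` reports, per zone, 100·mean over bins of
(interp − raw)/interp, skipping bins with a zero denominator (they are
neither 0% nor 100%). The interpolated count is the default denominator
(the "completed" series); a raw-denominator variant is switchable. The
per-bin added-user series is returned alongside so the expected
concentration of bias in the early year (head back-fill) can be
inspected.

`low_frequency_fraction` z-scores a series, takes the real DFT, discards
the zero-frequency term and reports the share of remaining power in the
lowest `cutoff_fraction` of positive frequencies (at least one). Values
near 1 justify coarse time bins: the seasonal content survives
aggregation.

## Selection

Visitors of a zone are classified by months stayed: occasional (1),
moving/migratory (2–11), permanent (12). Class ratios per zone partition
the zone's visitors exactly.

The radius of gyration r_g is the RMS distance of the user's 365
(interpolated) daily positions from their visit-weighted mean, computed
in a local equirectangular plane around that mean, with equal day
weights. This daily-row basis is fully reproducible from the IT-Matrix;
toolboxes that work from raw records weight by event counts instead and
may differ slightly.

A user is flagged a **regular traveler** when the largest centroid
distance among consecutive-day region changes is ≤ `ratio × r_g`
(default ratio 3): their moves are routine at their own scale. Users with
no changes are regular; users with changes but r_g = 0 are not. Note the
filter's geometry: a two-location trajectory splitting the year p/(1−p)
between places distance d apart has r_g = d·√(p(1−p)), so at ratio 3 any
split with √(p(1−p)) > 1/3 — i.e. more than about 1.5 months away — is
flagged "regular" and removed. The filter is therefore very sensitive to
the threshold and to region sizes; analyses targeting multi-month
migrants should lower the ratio (the synthetic validation scenarios use
1.0, which keeps every two-location migrant since a single long move is
always at least 2·r_g).

Selection stages, applied in order to the target zone's visitors:
non-movers (if enabled), regular travelers, urban residents (if enabled;
residence region = mode of the interpolated daily regions, flagged
urban), minimum consecutive months in target (non-wrapping: December and
January are not consecutive), maximum total months, minimum months in
some *single* other zone (switchable to the sum over other zones), and
presence in the target during *every* month of an optional required
period. The audit lists users removed per stage; removed counts sum to
visitors − selected.

Binarized profiles (1 iff the month's preferential zone is the target)
are guaranteed ≥ 1 one per row by selection; an all-zero row is a
contract violation and raises.

## Profile clustering

Pairwise Jaccard distance between binary rows (undefined, and an error,
for two all-zero vectors — excluded by the selection contract) feeds
agglomerative hierarchical clustering. The dendrogram is cut after
exactly n − k merges, which always yields k clusters even when merge
heights tie (a threshold-based cut can skip past k). Labels are
reassigned by decreasing cluster size, ties broken by the smallest
first-member row index, so output labels are permutation-stable up to
the documented tie-breaks. Duplicate rows have distance 0 and merge
first; no jitter is added.

Average linkage is the default; complete linkage behaves similarly on
separated groups. **Ward** linkage is offered for parity with common
practice but is applied to a non-Euclidean (Jaccard) distance matrix,
where its variance-minimizing interpretation does not hold; treat its
results as heuristic. `k` is user-chosen (typical analyses use 3 or 4);
no automatic model selection is attempted, though the cophenetic
correlation is reported as a clustering-quality summary.

## Fusion with external series

External zone-level series (monthly rainfall, vegetation index, digitized
income calendars — any numeric zone × bin table) are z-scored onto the
signature scale. `correlate` pairs a[t] with b[t+lag] over the
overlapping window (no wrap-around) for each lag in ±`lag_range`,
reporting Pearson (or Spearman) coefficients and window lengths; windows
shorter than 3 bins or constant are flagged undefined. The alignment
report dates the external onset as the first bin reaching 0.5 of the
series peak (the fraction is a parameter; onsets are inherently
qualitative) and each profile's switch as the later month of its largest
absolute month-over-month change, reporting the signed change and the
lag. Correlations are descriptive; no multiple-testing correction is
applied.

## Synthetic generator

The generator emulates the *structure* of a year-long operator release:
123 regions / 13 zones by default (zone 1 urban, zone centers on a
coarse grid near Senegal with regions jittered within ±0.15°), planted
behavioral groups (permanent residents, occasional one-month visitors,
seasonal migrants with departure/return months), per-day inactivity
(default 0.2), Poisson event counts on active days (mean 4, floor 1),
uniform 10-minute tick placement, a minimum-active-days floor (default
256, mirroring upstream operator filtering), and within-zone region
choice that is uniform per month and fixed inside the month. Flip noise
(used at 0.05 by the clustering validation scenario) independently
toggles single months of a user's itinerary between the template and its
alternate zone. All sampling comes from one seeded stream in a fixed
order, so outputs — including emitted files — are byte-identical per
seed.

What it does **not** emulate: social call structure, antenna-level
spatial noise, within-day movement, event-rate heterogeneity between
users, overseas visitors, or any correlation between phone activity and
location. Passing tests therefore demonstrate that the pipeline recovers
planted structure under realistic sampling and missingness — not that
real populations behave like the templates.

Validation problem sizes were chosen to exercise each contract at
desk scale: 300 users for clustering recovery, 2,000 for visitor-class
fractions, 1,000 for count conservation, 200 random instances for the
mode-reduction oracles.

## Known limitations

* Home-location refinement by hour-of-day (night hours weighting) is not
  implemented; the daily preferential region is used as the home
  estimator throughout.
* The regular-traveler filter at its default ratio removes multi-month
  two-location migrants (see above); it is kept for fidelity to common
  practice but should be re-parametrized per analysis.
* Zone assignment, urban flags and external series are consumed as
  tables; no raster, shapefile or satellite processing is included.
* One calendar year of data supports no between-year baseline; the
  correlation and alignment outputs are descriptive single-year
  summaries.
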