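# cdrmobility

Seasonal mobility profiling from anonymized, region-quantized call-detail
records (CDRs).

Year-long CDR releases — one record per call with an opaque user id, a
timestamp quantized to 10-minute ticks and the administrative region
serving the call — carry enough signal to measure *seasonal migration*:
who leaves a rural zone at the start of the rainy season, who arrives for
the harvest, how a city's population swells in summer. Such measurements
feed food-security early warning, where ground surveys are expensive and
slow. `cdrmobility` implements the full chain from raw event files to
clustered seasonal mobility profiles, plus a seeded synthetic-CDR
generator so the whole pipeline can be exercised and validated without
access to any operator data.

## Method

The central object is the **individual-trajectories matrix (IT-Matrix)**:
an *N* × *N*<sub>T</sub> matrix whose row *p* is user *p*'s preferential
location per time bin. From per-user event vectors
*q*<sub>p</sub> = [*Q*(*x*<sub>p</sub>(*t*<sub>p,1</sub>)), …,
*Q*(*x*<sub>p</sub>(*t*<sub>p,n<sub>p</sub></sub>))] the pipeline:

1. **Regularizes to daily resolution** — cell (*p*, *d*) is the region
   with the most call events by user *p* on day *d* (the daily
   preferential region, an estimator of the latent home location
   *h*<sub>p</sub>); a day with no events is missing.
2. **Interpolates missing days** with the last known position; a leading
   gap is back-filled with the first active day's value. The added
   presence is audited as a per-zone *interpolation bias*
   100·mean<sub>t</sub>(interp−raw)/interp.
3. **Aggregates** in time (per-window mode → 365 / 53 / 24 / 12 bins for
   daily / weekly / biweekly / monthly) and in space (regions → analysis
   zones through a many-to-one map). Counting users per zone per bin
   yields a **dynamic population count**; z-scoring each zone's series
   gives its seasonal signature.
4. **Selects** each target zone's moving population: visitors classified
   by months stayed (occasional = 1, moving = 2–11, permanent = 12),
   optional removal of non-movers, of "regular travelers" (largest
   inter-day move ≤ ratio × radius of gyration *r*<sub>g</sub>), of urban
   residents, then four temporal constraints on the monthly zone sequence
   (minimum consecutive months in target, maximum total months, minimum
   months in another zone, required presence months).
5. **Clusters** the selected users' binarized monthly profiles (1 iff the
   month's preferential zone is the target) with agglomerative
   hierarchical clustering on pairwise **Jaccard distance**
   1 − |a∧b|/|a∨b|, cut at *k* clusters. Each cluster is a mobility
   profile; its monthly in-zone count curve is the profile's seasonal
   fingerprint.
6. **Fuses** profiles with external zone-level series (rainfall,
   vegetation index): z-score rescaling, lagged Pearson correlation, and
   an event-alignment report comparing the series onset month with the
   month of each profile's largest change.

## Worked example

```python
import cdrmobility as cm

# three planted profile groups (100 users each) around target zone 11
sc = cm.generate(cm.clustering_scenario(seed=42))
print(f"events: {sc.events.n_events}  users: {sc.events.n_users}")

daily = cm.interpolate_missing(
    cm.daily_preferential(sc.events, sc.calendar, sc.partition))
mpl = cm.aggregate_space(cm.aggregate_time(daily, "monthly"), sc.partition)
print(f"monthly zone matrix: {mpl.values.shape}")

sel = cm.select_users(mpl, daily, sc.partition,
                      cm.SelectionConfig(target_zone=11,
                                         rog_ratio_threshold=1.0))
print(f"selected {sel.n_selected} of {sel.n_visitors} visitors of zone 11")

B = cm.binarize(mpl, sel, sc.partition)
ps = cm.hierarchical_profiles(B, k=3, linkage="average")
print(f"cluster sizes: {ps.sizes}")
for c in range(3):
    print(f"profile {c + 1} monthly in-zone counts:", ps.curves[c])
```

prints

```
events: 352556  users: 300
monthly zone matrix: (300, 12)
selected 300 of 300 visitors of zone 11
cluster sizes: [101 100  99]
profile 1 monthly in-zone counts: [91 96 96 97 95 97  4  7 10  0  5  6]
profile 2 monthly in-zone counts: [ 4  5  5  4  2  4 95 98 95 95 94 93]
profile 3 monthly in-zone counts: [ 9  5  3 95 95 92 98 92 91  1  3  7]
```

The three recovered profiles match the planted behaviors — residents
present January–June, second-half visitors, and mid-year visitors — with
the planted 5% month-flip noise visible as small off-template counts.

The same workflow is available from a shell:

```bash
cdrmobility simulate --out sim --seed 42 --scenario clustering
cdrmobility cluster --events sim/events.csv --partition sim/partition.csv \
    --zone 11 --k 3 --rog-ratio 1.0 --out-prefix profiles_z11
```

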