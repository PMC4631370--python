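# emaccess

Population-level spatial access to emergency health services.

Many low- and middle-income countries have no routine data on how far their
populations live from facilities that can actually deliver emergency care.
`emaccess` implements the standard GIS workflow for answering that question
at national scale, as a tested, scriptable library instead of a desktop GIS
session. It is aimed at health-systems and injury-epidemiology researchers
working with facility audit data (Service Provision Assessment–style
surveys), digitized road networks, and gridded population surfaces
(WorldPop-style rasters).

## What it computes

1. **Facility capability classification.** Each audited facility is
   assigned overlapping capability flags from fixed criteria (derived from
   the WHO Integrated Management for Emergency and Essential Surgical Care
   toolkit):
   - **Level A** (24-hour emergency services): overnight beds, 24-hour duty
     schedule, ≥ 2 qualified providers (specialist physicians, medical
     officers, or nurses), water, electricity, functioning telephone,
     on-site latrines;
   - **Level B** (resuscitative capability): all Level A criteria plus IV
     fluids, blood products, basic surgical instruments (forceps, needle
     driver, sterile scissors), local anesthesia, sterile dressings,
     supplemental oxygen;
   - **Level C** (tertiary care): a tertiary hospital designation, *or* all
     Level B criteria with > 50 inpatient beds and a surgeon on staff;
   - **Level X**: none of the above (excluded from catchment analysis).

2. **Network-distance service areas.** Road polylines are planarized
   (every intersection becomes a node), facilities are snapped to the
   nearest edge, and the subnetwork within a distance cutoff *r* ∈ {5, 10,
   50 km} of the capable facilities is extracted by multi-source Dijkstra
   with exact partial-edge interpolation. The reached geometry is buffered
   by 1,000 m to capture people living near, but not exactly on, mapped
   roads.

3. **Zonal population coverage.** For each level × cutoff, the proportion
   of the national and of each administrative region's population whose
   raster cell center falls inside the buffered catchment:

   p(level, r) = Σ pop(cells ∩ buffered catchment) / Σ pop(cells).

4. **Uncertainty intervals (UI).** The 1,000 m buffer is shrunk and grown
   by ±50% and coverage recomputed; the min/max of the three runs bracket
   each proportion.

5. **Euclidean comparison.** The same coverage computed with plain disks
   of radius *r* around facilities (no network), the classical concordance
   check on road-network completeness.

A synthetic-country generator (settlement-clustered populations, trunk +
branch road networks, Voronoi regions, capability prevalences decreasing
sharply from A to C) makes the entire pipeline reproducible and testable
without any restricted data download.

## Worked example

```python
from emaccess.facilities import classify_roster
from emaccess.pipeline import coverage_table
from emaccess.roadnet import build_network
from emaccess.synthetic import dense_spec, generate_country

country = generate_country(dense_spec(seed=7))
profiles, summary = classify_roster(country.facilities)
print(summary.to_string(index=False))

network = build_network(country.roads)
result = coverage_table(country.facilities, profiles, network,
                        country.raster, country.regions)
t = result.table
print(t[t.scope == "national"].to_string(index=False))
```

prints

```
level  count   percent
    A      8 26.666667
    B      3 10.000000
    C      1  3.333333
    X     22 73.333333
   scope level  cutoff_km  proportion   ui_low  ui_high
national     A        5.0    0.334827 0.202943 0.427627
national     A       10.0    0.362043 0.216687 0.468995
national     A       50.0    0.492905 0.297206 0.628782
national     B        5.0    0.200909 0.123929 0.254068
national     B       10.0    0.226098 0.135956 0.295361
national     B       50.0    0.492905 0.297206 0.628782
national     C        5.0    0.092487 0.057193 0.117989
national     C       10.0    0.098237 0.060247 0.126485
national     C       50.0    0.375733 0.225907 0.480034
```

Reading the table: 8 of this synthetic country's 30 facilities qualify for
24-hour care (Level A; the counts overlap — every Level B facility is also
Level A), and 49.3% (UI 29.7–62.9%) of the population lives within 50 km of
road travel of one, while only 37.6% is within 50 km of tertiary care.
Per-region rows (scope = region id) follow the national rows; regions with
no population are reported as N/A. `write_report` emits a full-precision
CSV plus a display CSV rounded half-up to one decimal in percent.

The same workflow is available from the shell:

```sh
emaccess simulate --preset dense --seed 7 --out country/
emaccess classify --facilities country/facilities.csv --out profiles.csv
emaccess coverage --config config.yaml --out results/
emaccess euclidean --config config.yaml --out results/
```

where `config.yaml` names the four input files and any non-default
parameters (`cutoffs_km`, `buffer_m`, `ui_factor`, `max_snap_m`,
`missing_policy`, ...).

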