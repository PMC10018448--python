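# ionarchive

SQL archiving and reanalysis of untargeted LC-HRMS<sup>E</sup> ion signals.

High-resolution LC-MS screening labs (forensic toxicology, clinical and
environmental monitoring) acquire data-independent MS<sup>E</sup> data —
alternating low-collision-energy scans of intact ions and high-energy scans
of fragments — for years with one stable method. The data is rich: every
analyte leaves a protonated molecule [M+H]⁺, isotopes, adducts, in-source
fragments (low energy) and diagnostic fragment ions (high energy). But
vendor software locks those ions inside per-batch "components", so asking a
new question of old data normally means reprocessing thousands of raw files.

`ionarchive` implements the alternative: **decomponentize** the processed
peak data — every measured ion becomes one row of a two-table SQL archive
(`samples`: one row per injection; `peaks`: one row per ion with accurate
mass, retention time, intensity and energy channel) — and make the closed
tolerance window

&nbsp;&nbsp;&nbsp;&nbsp;|m/z − m/z₀| ≤ 3 mDa,&nbsp;&nbsp; |RT − RT₀| ≤ 0.5 min

the universal query primitive. On top of that primitive it provides:

- **QC-gated ingestion** — a run enters the archive only if every non-blank
  injection contains every internal standard, methanolic QC mixes
  (~100 standards) are detected at ≥ 90%, and blanks are clean; the insert
  is atomic.
- **Retrospective screening** — a newly defined target (precursor m/z,
  library RT, one diagnostic fragment) is screened against every archived
  injection in seconds: a low-energy precursor within ±3 mDa plus a
  high-energy fragment co-eluting within 0.015 min; results are scored
  against truth from a complementary quantitative method.
- **Long-term QC monitoring** — mass/RT deviation series of internal
  standards with 1 mDa / 0.25 min evaluation windows, fragment-to-precursor
  reproducibility per channel, and RT-drift flags (±0.5 min band) annotated
  with maintenance events.
- **ScreenOmics discovery** — for analytes that ionize poorly, ions of
  known-positive vs known-negative cohorts are scaled by the tolerances
  (u = m/z / 3 mDa, v = RT / 0.5 min), clustered by flat-kernel **mean
  shift with bandwidth 1**, and ranked purely by cohort occupancy
  (occupancy<sub>pos</sub> − occupancy<sub>neg</sub>; intensities are never
  consulted), surfacing alternative targets such as adducts and in-source
  fragments.
- **A seeded synthetic MS<sup>E</sup> generator** — instrument-grade ground
  truth (mass noise, RT drift, lognormal intensity noise, detection floor,
  contaminant background, dosed compounds with restricted ion roles) so
  every workflow is exercisable and testable at desk scale.

## Worked example

```python
from ionarchive import (IonWindow, deviation_series, deviation_summary,
                        simulate_archive)
from ionarchive.synthetic import default_design, target_for

# three batches on rotating instruments: blanks, IS blank, 3 methanolic QCs
# and 20 cases per batch, internal standards in every injection
design = default_design(seed=42, n_batches=3, cases_per_batch=20)
res = simulate_archive(design)          # every batch passes the QC gate
print(res.store.n_samples(), res.store.n_peaks())   # 75 6951

# monitor the cocaine-d3 internal standard across the whole archive
std = target_for(design.internal_standards[3], with_fragment=False)
series = deviation_series(res.store, std)
print(len(series.points), len(series.missing))      # 75 0
s = deviation_summary(series.points)
print(f"{s.mass_sd*1000:.3f} mDa, {s.rt_sd:.3f} min, "
      f"{s.frac_mass_within_window:.3f}")           # 0.549 mDa, 0.044 min, 0.920

# the universal primitive: a closed ±3 mDa x RT window query
hits = res.store.query_ions(
    IonWindow(std.precursor_mz, 0.003, 4.75, 5.75, channel="low"))
print(len(hits))                                    # 75
```

The archive holds 75 injections and 6,951 ion rows; the internal standard is
found in all 75 (none silently dropped), its recovered mass-error SD
(0.549 mDa) and RT-error SD (0.044 min) match the simulated instrument noise
(0.5 mDa, 0.05 min), and 92% of mass errors sit inside the 1 mDa QC window —
close to the Gaussian expectation of 95.4% at this n. The window query
returns exactly one precursor ion per injection.

The same operations are available from the shell:

```bash
ionarchive simulate --seed 42 --batches 3 --out runs/
ionarchive init archive.db
ionarchive ingest archive.db runs/run000 --standards runs/standards.csv
ionarchive query archive.db --mz 307.1732 --tol-mda 3 --rt 5.25 --rt-window 0.5
ionarchive screen archive.db --targets runs/standards.csv --out detections.csv
ionarchive monitor archive.db --standard one_standard.csv --out deviations.csv
ionarchive discover archive.db --positives pos.txt --negatives neg.txt --out candidates.csv
```

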