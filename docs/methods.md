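# Methods

## The archive model

An MS<sup>E</sup> acquisition alternates a low-collision-energy scan (intact
ions: protonated molecule, isotopes, adducts, in-source fragments) and a
high-collision-energy scan (residual precursor plus fragment ions) without
precursor isolation. Vendor processing groups co-eluting ions from both
channels into *components*. `ionarchive` stores the output of that upstream
step — it performs no peak picking, centroiding, lock-mass correction or
componentization itself — and *decomponentizes* it: each ion becomes an
independent row of the `peaks` table (accurate mass, retention time,
intensity, channel, optional ion role), with its source component id kept as
provenance only. No operation in the package ever joins back to component
structure; this is the contract that keeps all data layers queryable for
questions the original processing never anticipated.

Two tables, `samples` and `peaks`, are held in an embedded SQLite file (any
SQL engine would do; SQLite keeps the test surface server-free) with indices
on m/z, RT and sample id. The universal read primitive is a **closed**
window query: `|mz − mz₀| ≤ tol` and `rt_lo ≤ rt ≤ rt_hi`, optionally
filtered by channel and sample. Closed intervals are applied uniformly —
an ion at exactly +3 mDa or a fragment at exactly +0.015 min is inside.
Mass tolerances are absolute (Da), not ppm. Query order is deterministic:
`(sample_id, rt, mz, peak_id)`.

## Tolerance constants

| parameter | default | role |
|---|---|---|
| `mass_tol` | 3 mDa | precursor/fragment matching, scaling before clustering |
| `rt_tol` | 0.5 min | RT matching window, scaling before clustering |
| `coelution_tol` | 0.015 min | fragment-to-precursor grouping |
| `bandwidth` | 1 (scaled units) | mean-shift kernel radius |
| `qc_mass_window` | 1 mDa | QC evaluation window on mass errors |
| `qc_rt_window` | 0.25 min | QC evaluation window on RT errors |
| `drift_rt_window` | 0.5 min | RT band beyond which a point is flagged drifted |

The 1 mDa / 0.25 min windows are *evaluation* windows for QC statistics;
detection windows for screening remain 3 mDa / 0.5 min. This distinction is
deliberate: QC windows describe how well the system performs, detection
windows how far a match may stray before it is discarded.

## QC gate

The forensic rule "only runs that fulfilled QC criteria enter the archive"
is operationalized with three checks built from the monitored quantities:

a. every case / IS-blank / methanolic-QC injection contains every internal
   standard's precursor within ±`mass_tol` and ±`rt_tol`;
b. each methanolic QC injection detects ≥ 90% (configurable) of the QC-mix
   compounds;
c. blank samples contain no QC-mix precursor above a configurable intensity
   floor (default 0: any signal fails).

All thresholds are configuration, not constants, because real laboratories
tune them. Ingest is atomic — one SQL transaction covers the sample and peak
inserts, so a crash or refusal leaves the store byte-identical.

## Screening rules

Detection of a target in a sample requires a low-energy precursor ion inside
±`mass_tol` (and inside ±`rt_window` of the library RT when both are set;
default window ±0.5 min). Among multiple in-window candidates the smallest
|Δm/z| wins, ties broken by higher intensity — the choice is unstated in
practice and fixed here for determinism. When the target declares a
diagnostic fragment, a high-energy ion within ±`mass_tol` of the fragment
m/z must co-elute with the *chosen* precursor within ±`coelution_tol`;
high-energy only, matching the channel roles of MS<sup>E</sup> (diagnostic
fragments live in the high-energy scan; the low-energy analogue is the
in-source fragment, a different ion role). Retrospective evaluation counts
truth-positive detections absent from the original case findings as
*tentative positives*; previously known detections are tracked separately so
the counts always partition the evaluations.

## QC monitoring

Deviation series use the screening match rules but a widened RT search
window (3 × `rt_tol` = 1.5 min): a standard that has drifted past the
±0.5 min action band must still be *measured* so it can be *flagged*;
with the plain detection window it would silently go missing. Injections
where the standard is genuinely absent are reported as missing, never as
zero-error points. Fragmentation reproducibility is summarized as
fragment-to-precursor intensity ratio per energy channel (in the high-energy
channel the reference is the residual precursor) — the ratio is the natural
scale-free quantity a QC chart needs; the metric choice is ours and is
documented as such. Drift flagging is plain thresholding against
`drift_rt_window` with optional annotation by the most recent preceding
maintenance event; changepoint detection is out of scope.

## ScreenOmics

Low-energy ions of the two cohorts are scaled to dimensionless coordinates
u = m/z / `mass_tol`, v = RT / `rt_tol`, so one tolerance in either axis is
unit distance. Mean shift with a **flat kernel** and bandwidth 1 then finds
the recurring ion positions:

- every point iteratively moves to the mean of all original points within
  Euclidean distance ≤ bandwidth of its current position;
- a point stops when its displacement falls below 1e−3 · bandwidth, with a
  global cap of 300 iterations;
- converged positions are merged deterministically: processed in
  lexicographic (u, v) order, a position joins the nearest existing mode if
  within bandwidth/2, else founds a new mode; final modes are sorted by
  (u, v).

Kernel shape, convergence tolerance, merge radius and tie rules are not
dictated by the problem; they are fixed as above so that results are
reproducible and order-independent, and the test suite holds the
implementation to an independently written per-point fixed-point iteration
(and cross-checks cluster partitions against scikit-learn's mean shift on
separated data).

Clusters are ranked by `occupancy_pos − occupancy_neg`, where occupancy is
the fraction of a cohort's samples containing the cluster. Intensities are
never consulted — presence/absence across many controls is the signal, which
is exactly what makes the approach work for poorly ionized analytes whose
alternative ions (ammonium adducts, in-source fragments) are reproducible
but weak. Clusters occupying more than 5% (configurable) of the negatives
are suppressed as background before ranking; internal standards, which sit
in every sample, die there. High-energy ions co-eluting with a candidate's
mode RT within ±`coelution_tol` in the cluster's own samples are attached as
candidate diagnostic fragments, deduplicated by m/z within ±`mass_tol` (most
intense representative). Only low-energy ions enter clustering — co-
clustering both channels would let abundant fragments absorb precursor
clusters; fragment attachment afterward respects the channel roles.

## Synthetic data generator

The generator is the package's study-condition definition, not a test prop.
Per compound and injection it emits one component spanning both channels:
[M+H]⁺ (proton mass 1.007276 Da), an M+1 isotope at 1.07% per carbon
(+1.003355 Da), declared adducts and in-source fragments (low energy), a
residual precursor at 0.3 × the precursor intensity and declared fragments
(high energy). Noise model:

- mass: additive Gaussian, `mass_sd` (default 0.5 mDa) per ion;
- RT: one draw per compound and injection — true RT + per-batch drift
  (constant slope, step sequence, or callable) + Gaussian `rt_sd` (default
  0.05 min) — shared by all of the compound's ions in both channels, so
  within-component co-elution is exact;
- intensity: lognormal multiplicative noise with CV 0.2 (no intensity model
  is established for this data; lognormal is the standard heteroscedastic
  choice), fragments additionally carry Normal(1, `fragment_yield_sd`)
  yield noise relative to the measured precursor, so fragment/precursor
  ratios recover the yield spread directly;
- ions below the detection floor (50 counts) are dropped but recorded in
  the truth table as planted-yet-invisible;
- contaminants: homogeneous Poisson background (default 20 ions/sample,
  m/z ∈ [100, 1000], RT ∈ [0, 15 min]), one single-ion component each.

Batch layout mirrors routine screening: one blank matrix, one IS blank,
three methanolic QC injections (~100-compound mix at fixed chemistry,
generated once from a frozen seed) and the case samples; internal standards
(five deuterated drugs with formula-derived masses) in every injection;
instruments rotate across batches; run time 15 min. A dosed compound is
planted in a Bernoulli fraction of cases and may be restricted to a subset
of ion roles — the mechanism behind the discovery tests, emulating an
analyte visible only as an adduct and an in-source fragment. Everything is
a pure function of `(seed, batch_index)`.

What the generator does **not** emulate: chromatographic peak shapes,
profile spectra, chimeric spectra, full isotope patterns, correlated matrix
effects, or real co-elution jitter between channels. Passing tests
therefore demonstrate the correctness of the archive logic, the window
semantics, the statistics and the clustering under the stated noise model —
not performance on real instrument output, where componentization artifacts
and matrix interferences add failure modes this model does not contain.

## Numerical and design choices

- All tolerance comparisons are closed; boundary ions count as inside.
- Candidate selection (smallest |Δm/z|, then intensity, then row id) makes
  every operation deterministic, including under exact ties.
- The deviation search window (3 × `rt_tol`) and the fragmentation metric
  are interpretations, flagged above.
- Problem sizes in the test suite and the acceptance script (e.g. a
  1,000-injection archive at ~200 ions per injection, 1,000 randomized
  query windows, 10-seed screening studies) were chosen as the smallest
  scales at which the statistical assertions (SD recovery within 10%,
  binomial/Gaussian checks within 3 SE) have adequate power.
- `mz_sd`/`rt_sd` columns exist to carry upstream per-ion variance
  estimates when a source provides them; no operation depends on them.

## Known limitations

- The component-file dialect (CSV/JSON, version 1) is a stand-in for
  proprietary vendor exports; a converter from mzML-derived centroid peak
  lists is a natural extension but peak picking itself stays out of scope.
- Occupancy differences are reported without significance testing;
  control-chart rules for QC series are likewise out of scope.
- Mean shift is exact (no bin seeding); on archives of millions of ions a
  pre-windowed run (`cluster_archive(..., mz_window=...)`) is the intended
  entry point, and both entry points are exposed.
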