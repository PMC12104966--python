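# lynxmon

Quantitative monitoring machinery for large-carnivore translocation programs,
built around the restoration of a small, inbred Eurasian lynx (*Lynx lynx*)
population reinforced with wild-caught immigrants. The package bundles the
four analysis stages such a program runs year after year, plus seeded
synthetic-data generators so every stage can be exercised and validated
without any field data:

* **`lynxmon.popgen`** — microsatellite genetic monitoring: observed and
  Nei's unbiased expected heterozygosity, *effective inbreeding*
  `Fe = 1 − H_focal / H_ref` against a source-population reference
  (default `H_ref = 0.592`), the lethal-equivalents projection of inbreeding
  depression `δ = 1 − exp(−B·Fe)` with `2B = 12` diploid lethal equivalents
  and relative fitness `1 − δ`, a 40-individual traveling window that turns a
  chronological genotype series into an Fe/fitness trajectory, reinforcement
  scenarios (remnant-only, core reinforcement, fully connected
  stepping-stone), immigrant-ancestry detection via private alleles, and
  parentage assignment by simple allele exclusion.
* **`lynxmon.scr`** — maximum-likelihood spatial capture–recapture on
  camera-trap data: a half-normal encounter model
  `p = p0 · exp(−d²/2σ²)` over a buffered state-space lattice (defaults
  15 km buffer, 2.5 km cells), covariates on `p0` (session, sex, camera-site
  type, trap-specific behavioral response *b*) and on `σ` (sex), a
  conditional-on-detection likelihood with Horvitz–Thompson abundance and
  density per 100 km², AIC model ranking, the Aug 15–Feb 15 closure-season
  filter, and annual turnover.
* **`lynxmon.predation`** — GPS-location-cluster (GLC) kill-site detection
  (200 m radius, 2-day window, ≥2 fixes), inter-kill intervals, feeding
  times, time to first kill after release, and brown-bear kleptoparasitism
  rates with exact binomial confidence intervals.
* **`lynxmon.survival`** — Kaplan–Meier survival over GPS-tracking periods
  with the telemetry end-status taxonomy (alive / disappeared / suspected or
  confirmed illegal killing / roadkill / natural mortality), selectable
  censoring policies, Greenwood standard errors, and the k-sample log-rank
  test.
* **`lynxmon.synthdata`** — generators with truth sidecars: a
  founder-bottleneck Wright–Fisher population with staged immigrant
  reinforcement, a half-normal SCR sampler, two-phase (kill/travel) GPS
  tracks, and censored group survival times.
* **`lynxmon.io` / `lynxmon.report` / `lynxmon` CLI** — plain-CSV
  readers/writers for every data family, a YAML-configured pipeline with a
  human-readable summary, and a thin `lynxmon` command with `synth`,
  `popgen`, `scr`, `glc`, `survival` and `report` subcommands.

The intended users are monitoring scientists and analysts in reintroduction
or reinforcement projects who need the same estimates every season —
inbreeding trajectories, density, predation metrics, survival — from
field-standard CSV inputs.

## Worked example

`examples/inbreeding_trajectory.py` builds a synthetic bottlenecked
population reinforced with outbred immigrants and tracks effective
inbreeding under the three scenarios:

```
273 genotyped individuals, 19 microsatellite loci

          remnant_only: final-window Fe = +0.554, delta = 0.96, relative fitness = 0.04
 dinaric_reinforcement: final-window Fe = -0.079, delta = 0.00, relative fitness = 1.00
       fully_connected: final-window Fe = -0.251, delta = 0.00, relative fitness = 1.00
```

Without reinforcement the simulated population keeps losing heterozygosity
(final-window Fe 0.55, i.e. a projected 96 % fitness loss at 12 diploid
lethal equivalents); including the translocated animals and their offspring
pushes the final window's heterozygosity back to — here slightly above — the
source-population reference (negative Fe is reported as-is and δ is
evaluated at `max(Fe, 0)`). The fully connected scenario, which merges the
stepping-stone subpopulation, ends lowest. The closed-form projection
itself maps `Fe = 0.32 → δ = 0.85` and `Fe = 0.19 → δ = 0.68`:

```python
>>> from lynxmon.popgen import inbreeding_depression
>>> round(inbreeding_depression(0.32, 12.0), 2)
0.85
```

The other example scripts each exercise one stage end to end
(`density_estimation.py`, `kill_site_detection.py`, `survival_analysis.py`,
`full_pipeline.py`) and print both the estimate and the simulated truth it
should recover.

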