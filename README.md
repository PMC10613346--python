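# meniscometry

3D knee-meniscus morphometry from segmented label volumes.

Given a NIfTI label map containing the medial meniscus, lateral meniscus and
tibial plateau cartilage, the package measures three diagnostic indices on the
top-down (axial) footprint in anatomical mm space:

- **RMT** — minimum meniscal body width / maximum tibial width (`a / b`),
- **PCM** — covered fraction of the maximal AP diameter line
  (`(c + d) / e`, anterior + posterior horn runs over the AP diameter),
- **L/M ratio** — lateral / medial anteroposterior diameter (`L / M`),

classifies discoid lateral menisci by threshold (DLM at RMT ≥ 0.20, complete
DLM at RMT > 0.32, auxiliary coverage flag at PCM ≥ 0.75), and provides the
matching cohort statistics (Mann-Whitney U with an exact small-sample path,
Pearson χ² with Yates continuity correction, ICC(2,1) reliability).

Because clinical scans cannot be redistributed, validation rests on a
parametric **knee phantom generator**: C-shaped elliptical-annulus menisci
with a crescent → complete-discoid continuum (`coverage` parameter), an
elliptical tibial plateau, voxelization at the anisotropic acquisition
geometry (0.35 × 0.35 × 0.7 mm), seeded smooth boundary jitter, and
analytically known ground-truth morphometry for every generated knee.
Whole two-group cohorts with controlled between-group differences can be
sampled from truncated-normal parameter distributions.

## Conventions

- All measurements are taken in anatomical mm space: x = medial–lateral,
  y = posterior–anterior (+y anterior), z = inferior–superior. Input volumes
  are reoriented to this RAS-like frame on load; left knees are mirrored
  across the ML axis so the lateral compartment is always at +x.
- A voxel is a closed box centred on its mm-space centre: an n-voxel run has
  length n × spacing.
- Default label encoding `{1: medial_meniscus, 2: lateral_meniscus,
  3: tibial_plateau}` is remappable via `--labels`.
- The "body" region for the minimum-width measurement is the central third of
  the AP extent (configurable via `--body-fraction`).

## CLI

```sh
# one synthetic knee (or --cohort for a full two-group cohort) + ground truth
meniscometry phantom --kind non_dlm --seed 7 --out-dir out/phantoms
meniscometry phantom --cohort --n-dlm 31 --n-non-dlm 43 --seed 7 --out-dir out/cohort

# measure every volume in a directory -> one CSV row per knee
meniscometry measure --input out/cohort --out out/measurements.csv

# re-apply (possibly customised) diagnostic thresholds
meniscometry classify --measurements out/measurements.csv --out out/classified.csv

# two-group comparison tables (Mann-Whitney; optional chi-square column)
meniscometry compare --measurements out/measurements.csv --out-prefix out/report

# ICC(2,1) from a wide rater x subject CSV
meniscometry icc --ratings ratings.csv --kind inter
```

`phantom` also accepts a TOML config (`--config`), e.g.

```toml
[phantom]
kind = "non_dlm"
jitter_mm = 0.3

[phantom.override]
"lateral.r_out_ap" = 16.0
"tibia_ml_semi" = 36.0
```

Every run logs its effective configuration, seed and version; identical
argv + seed reproduce identical outputs byte for byte.

## Layout

- `src/meniscometry/volume_io.py` — NIfTI label volumes, measurement and
  rating CSVs, orientation normalization.
- `src/meniscometry/phantom.py` — continuous shape model, voxelization,
  ground truth, cohort sampling.
- `src/meniscometry/morphometry.py` — footprint projection and the length /
  index operators.
- `src/meniscometry/classify.py` — threshold classification.
- `src/meniscometry/cohort_stats.py` — Mann-Whitney, χ², ICC, report tables.
- `src/meniscometry/cli.py` — subcommands above.
- `tests/` — unit, property and acceptance suites (`tests/test_acceptance.py`
  mirrors the acceptance criteria one test per criterion).
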