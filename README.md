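# forcebind

Quantification of **force-activated actin binding** in reconstituted
single-molecule assays.  Mechanosensitive actin-binding proteins (ABPs) such
as α-catenin associate more strongly with actin filaments under piconewton
tension.  Measuring that behavior requires two bespoke analysis pipelines,
both implemented here as a tested, headless Python library:

1. **TIRF filament-region quantification** (`forcebind.region_quant`).
   Dual-color TIRF movies record actin filaments agitated by
   surface-anchored myosin motors with a labeled ABP in solution.  The
   pipeline preprocesses the actin channel (unsharp mask, median filter,
   rolling-ball background subtraction), binarizes it, tracks connected
   "filament regions" across consecutive frames by nearest centroid under a
   24 px gate, keeps tracks of at least 10 consecutive frames whose
   centroids stay 30 px or more from the field-of-view edge, and computes
   per frame

   I<sub>ABP</sub>/I<sub>actin</sub> = (⟨ABP⟩<sub>region</sub> − bg<sub>ABP</sub>) / (⟨actin⟩<sub>region</sub> − bg<sub>actin</sub>),

   where each background is the mean of a 60 × 60 px window around the
   region's centroid excluding every detected region.  The track average of
   this ratio is the per-filament readout; the mean over tracks is the
   per-chamber summary entering paired −ATP/+ATP comparisons.

2. **Correlative trap force–fluorescence analysis**
   (`forcebind.trap_analysis`).  A filament tether strung between two
   optically trapped beads is pulled at constant velocity while 200 Hz
   force data and confocal frames are recorded.  The pipeline bins the
   two-trap mean force to the confocal frame interval, detects rupture
   events (≥ 1 pN drop within ≤ 5 samples), excludes multi-filament tethers
   (multiple rupture peaks; internal steps in the actin line scan;
   breaking force ≥ 16.5 pN), computes paired **low-force / high-force
   averages** (the mean ratio of the five frames before final rupture vs
   the five frames immediately preceding those), normalizes each recording
   by its maximum ratio, and finds the binding **force threshold** by
   K-means (k = 2) on standardized (force, normalized ratio) points — the
   midpoint between the clusters' force ranges — with silhouette scores for
   k ∈ {2, 3, 4} as the cluster-count diagnostic.

Support modules: `forcebind.stats_core` (exact Wilcoxon signed-rank by
complete enumeration of the signed-rank null, two-sample KS, silhouettes)
and `forcebind.synth_fixtures` (ground-truth synthetic movies and trap
recordings, so every stage is testable without any external dataset).

## Worked example

```bash
python examples/quantify_tirf_movie.py
```

```
3 filament tracks found (>= 10 consecutive frames each)

track  frames  recovered I_ABP/I_actin
    0      15  0.497
    1      15  1.497
    2      15  2.490

true ratios (ascending): [0.5, 1.5, 2.5]
chamber mean ratio: 1.495
```

The three tracked filaments were generated with true ABP/actin ratios 0.5,
1.5 and 2.5; the pipeline recovers each within ~1 % at the default
signal-to-noise level and preserves their ranking.  The other examples show
tether classification (`examples/classify_tethers.py`), force-threshold
detection with its silhouette and KS diagnostics
(`examples/detect_force_threshold.py`), and the exact paired test
(`examples/paired_chamber_test.py`), which prints, for seven chambers all
shifting the same way, the minimum attainable exact two-sided p-value
2/2⁷ = 0.0156.

A thin CLI mirrors the library for shell use:

```bash
forcebind synth-movie --seed 7 --out-prefix fix
forcebind quantify-movie --actin fix_actin.tif --abp fix_abp.tif --out-prefix run
forcebind paired-test --a before_summary.csv --b after_summary.csv
forcebind analyze-tether --force t_force.csv --frames t_frames.csv --line-scans t_scans.csv
forcebind threshold --points pooled.csv --seed 7
```

`quantify-movie` writes a detail CSV (one row per track and frame: 0-based
frame index, 0-based (row, col) centroid, area, background-subtracted
channel means, per-frame ratio), a summary CSV (one row per track with its
average ratio) and a JSON sidecar echoing the fully resolved configuration.

## Conventions

All pixel coordinates are 0-based `(row, col)`; frame indices are 0-based.
CSV floats are written in shortest round-trip decimal form, so re-reading a
table reproduces every float64 bit-for-bit.  See `docs/methods.md` for the
full description of the models, parameters and design choices.
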