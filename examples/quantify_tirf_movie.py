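"""Quantify filament-region intensity ratios in a synthetic dual-color TIRF movie.

Builds a movie with three filaments of known ABP/actin ratios, runs the full
detection / tracking / background-subtraction pipeline and compares the
recovered per-track average I_ABP/I_actin against the generator's truth.
"""

from forcebind.region_quant import quantify_movie, summarize_chamber
from forcebind.synth_fixtures import default_filament_specs, synth_movie

specs = default_filament_specs(true_ratios=(0.5, 1.5, 2.5), seed=1)
actin, abp, truth = synth_movie(specs, shape=(192, 192), n_frames=15, seed=1)

tracks = quantify_movie(actin, abp)
print(f"{len(tracks)} filament tracks found (>= 10 consecutive frames each)\n")
print("track  frames  recovered I_ABP/I_actin")
for t in sorted(tracks, key=lambda t: t.observations[0].centroid[0]):
    print(f"{t.track_id:5d}  {len(t):6d}  {t.average_ratio:.3f}")
print("\ntrue ratios (ascending):", sorted(float(r) for r in truth.true_ratio.unique()))
print(f"chamber mean ratio: {summarize_chamber(tracks):.3f}")
print("\nEach recovered value is the background-subtracted ABP/actin mean")
print("intensity ratio averaged over the track; it should sit within ~10%")
print("of the matching true ratio at the default signal-to-noise level.")
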