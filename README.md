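# fretpol

Spatiotemporal ratiometric FRET quantification for migrating and
phagocytosing cells imaged by TIRF microscopy.

Raichu-type biosensors report Rho-GTPase activity (e.g. Rac) as the
acceptor/donor emission ratio *R* = I(YFP)/I(CFP): GTP loading increases
FRET, so high *R* marks high activity.  Imaged at the basal cell surface by
TIRF with a two-camera emission splitter, such movies reveal where activity
sits in a polarized cell — at the leading edge, the uropod, the periphery or
a forming phagosome — and how that pattern moves on a seconds timescale.
`fretpol` turns a pair of donor/acceptor TIFF stacks into these numbers:

- **ratiometric core** — affine channel registration from bead calibration
  images, circular mean filtering (radius 2 px), guarded pixel-wise
  ratio *R* = acceptor/donor, 16-level pseudocolour rendering;
- **morphometry** — per-frame segmentation, area *A*, circularity
  *C* = 4πA/P², adherent-cell counts (objects < 40 µm² excluded),
  whole-cell mean *R*(t) and its AUC over a stated window (125 s default);
- **polarity dynamics** — line scans along the central longitudinal axis
  reduced to 20 bins (bin 1 at the leading edge), kymographs, 0.4 µm
  edge-band sampling, needle-aligned polar maps, and the per-frame peak of
  *R* along the axis with 0.8 µm pole-zone dwell times, pole-switch events
  and wave durations;
- **motility** — front-pixel velocity over 20 s windows, migrating/stalling
  phases (≥ 20 s periods with/without 2 µm centre-of-mass displacement),
  migration flags (≥ 7.8 µm in 2 min, or one cell diameter in 10 min),
  protrusion detection and micropipette turning latency;
- **phagocytosis** — 2 µm particle detection and tracking in brightfield,
  contact and full-engulfment timing, phagosome-annulus mean *R*, and
  fixed-scene uptake counts;
- **synthetic imaging** — a generator producing all of the above scenes
  with exact ground truth (15.6 µm polarized cell, pole-to-pole activity
  waves, programmed speeds, phases, protrusions and engulfment events,
  Poisson + read noise, channel misalignment), used by every recovery test.

## Worked example

Render a noiseless scene in which peak activity runs pole-to-pole with a
16 s full cycle, then recover the wave statistics through the full pipeline:

```python
from fretpol.scenes import oscillating_peak_scene
from fretpol.pipeline import analyze_movie
from fretpol.config import RunConfig

movie, truth = oscillating_peak_scene(full_cycle_s=16.0, n_frames=120,
                                      noise=False, seed=1)
bundle = analyze_movie(movie, RunConfig())
trace = bundle["peak_trace"]
print(f"pole switches:      {trace.n_switches}")
print(f"mean wave duration: {trace.mean_wave_s:.1f} s")
print(f"dwell at front:     {trace.dwell_front_s:.0f} s")
print(f"dwell at rear:      {trace.dwell_rear_s:.0f} s")
```

prints

```
pole switches:      14
mean wave duration: 8.0 s
dwell at front:     8 s
dwell at rear:      7 s
```

A 16 s pole-to-pole-and-back cycle contains two waves, so the pipeline
recovers a mean wave duration of 8.0 s; over 120 s the peak enters a pole
zone opposite the previous one 14 times, and at a 1 s frame interval it is
caught within 0.8 µm of each pole on roughly one frame per visit.

The same pipeline is scriptable from the shell:

```sh
fretpol simulate chemokinesis --seed 1 --out scene/
fretpol run scene/ --out results/
```

which writes per-cell CSVs (morphometry, kymograph, peak trace, phases,
movement path) plus a `summary.csv` and a run log with the fully resolved
configuration.

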