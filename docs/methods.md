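# Methods

## Ratiometric imaging model

A two-camera TIRF emission splitter records donor (CFP) and acceptor (YFP)
emission of a Raichu-type biosensor simultaneously.  Activity is the
pixel-wise ratio R = acceptor/donor, which cancels concentration and
path-length effects.  The processing order mirrors standard practice:
align the acceptor channel onto the donor, smooth both with a circular
mean filter, then divide.

**Registration.**  The inter-camera misalignment is modelled as a planar
affine transform estimated by least squares from bead centroids matched
between the two channels of a calibration image pair.  Beads are localized
by iterative intensity-weighted centroiding (sub-0.02 px noiseless).  An
affine model is a deliberate simplification of the elastic (B-spline)
registration sometimes used for beam splitters: the physical misalignment
(translation, small rotation, slight magnification difference) is well
captured by an affine map, which is exactly invertible and cheap to apply.
Fewer than three matched beads, or collinear beads, are rejected as
degenerate.  Resampling is bilinear; border samples with no source data
become invalid (NaN) rather than extrapolated.

**Smoothing.**  "Mean filter of two pixels" is read as the circular
neighbourhood of radius 2 px (13-pixel discrete disk); radius 0 is the
identity.  Whether the original convention was a radius or a 2x2 kernel is
not recoverable; the radius reading matches the common image-processing
convention and is recorded here as an open choice.  The filter is
NaN-aware (normalized by the valid-pixel count), so invalid borders do not
bleed into the cell.

**Division guard.**  The ratio is defined only where the donor clears a
floor — by default background + 3x read-noise SD when metadata is present,
else 1% of the donor dynamic range.  A floor avoids the low-signal bias an
additive epsilon would introduce.  No background subtraction is applied by
default; computing R on background-subtracted intensities is supported via
the floor parameter but is not the default because the acquisition
convention is unknown.

## Segmentation and shape

Cells are segmented per frame by Otsu thresholding of the smoothed donor
channel, hole filling, and watershed splitting of touching cells.  Watershed
markers are distance-transform maxima of prominence >= 0.4x the object's
maximum depth: two touching cells meet at a shallow saddle and are split,
while a protrusion bump merges smoothly into the body and is not — plain
minimum-distance markers were found to amputate protrusions from elongated
cells.  Area is pixel count x pixel_size^2.  The perimeter is the length of
the sub-pixel smoothed outline polygon (a circular moving average over 7
contour vertices knocks the half-pixel staircase of a binary boundary down
to ~0.1 px); circularity 4*pi*A/P^2 then stays within 0.05 of the analytic
value for both disks and 4:1 rectangles, where chain-code or Crofton
estimators err in opposite directions.  Circularity may exceed 1 by up to
0.05 for small rasterized disks; that tolerance is part of the contract.

Adhesion counts exclude objects *smaller than* 40 um^2 — an object of
exactly 40 um^2 is retained.

## Tracking and the longitudinal axis

The heading is the unit centroid displacement smoothed over a 5 s window;
a stationary cell falls back to its long (principal) axis, signed toward
the more protrusive end, then toward the previous heading, then +x.  For a
perfectly symmetric stationary cell the front/back assignment is therefore
arbitrary but frame-to-frame consistent, which is all the wave statistics
need.  Leading-edge and uropod anchors are the contour points extremal
along +/- heading, stabilized laterally by averaging the near-extremal arc
(flat tips otherwise jitter by ~1 px).

The central longitudinal axis is the chord through the centroid along the
heading, clipped to the mask — not a medial-axis skeleton — because it is
stable frame to frame and matches the line-scan convention.  The ratio is
sampled at <= 0.5 px spacing at bin-midpoint positions (an equal sample
count per bin, so the mean of the 20 bin values equals the profile mean
exactly), averaging across a 3-px band normal to the axis.  Bin 1 is at
the leading edge.

## Peak trace, pole zones and waves

The per-frame peak is the argmax of the *un-binned* axis profile.  Ties
break toward the previous frame's peak, then toward the leading edge, so
flat profiles cannot generate spurious switches.  Pole zones extend 0.8 um
along the axis from each anchor (inclusive).  A switch event is the peak
entering one pole zone after last having been in the opposite zone; no
switch is inferred across a gap of invalid frames.  A wave is the interval
between successive switches, so a full pole-to-pole-and-back cycle of
period T contains two waves of T/2 — a 16 s cycle yields 8 s waves.  The
oscillation count reported in output metadata is the number of switch
events; whether published counts were switches or full cycles is ambiguous,
and the convention is stated rather than guessed.  Dwell per pole is
frame_interval x frames with the peak in that zone, so front + rear +
interior dwell equals the observed time exactly.

Edge-band sampling averages in-mask pixels within 0.4 um of the contour
(euclidean distance transform), grouped into 360 angular bins of 1 degree
about the centroid (mathematical convention, 0 = east, counter-clockwise);
a band narrower than one pixel is widened to one pixel with a warning.
Polar maps rotate each frame's angular profile so the chemoattractant
needle sits due west (due south after a needle move), then stack frames as
eccentric circles, first frame innermost; maps combine across cells by
angular-bin mean.

## Motility

Chemokinesis phases follow the quantitative criterion: a frame is mobile
when the centre of mass displaces >= 2 um over the 20 s window centred on
it (windows are shifted, not shortened, near the track ends), and runs of
equal label lasting >= 20 s become migrating/stalling segments; shorter
remainders stay unlabeled.  The alternative lamella-based description of
phases is treated as interpretation, not as the classifier.  The simulator
derives its ground-truth phase labels from the *same* rule applied to the
true trajectory, so classifier-vs-truth agreement isolates tracking error.

Migration flags use net displacement over a stated observation period:
>= 7.8 um (half the mean body length) over 2 min, or >= one cell diameter
over 10 min, with "one cell diameter" operationalized as the
equivalent-circle diameter 2*sqrt(A_mean/pi) since no definition is given.
Front-pixel velocity is the leading-edge anchor displacement over sliding
20 s windows (the anchor is a deterministic, noise-robust stand-in for a
manually chosen brightest front pixel).

Protrusion events — a contiguous contour arc >= 2 um advancing outward at
>= 0.05 um/s for >= 5 s — are an automated proxy for manual counting; the
defaults are calibration choices validated only against the simulator.
Turning latency is the onset of the first protrusion after the needle move
whose arc direction lies within 45 degrees of the new source direction.

## Phagocytosis

Particles (2 um spheres) are detected in brightfield by
Laplacian-of-Gaussian blobs at the expected radius +/- 30% and linked by
nearest neighbour within one diameter; a detection with far more
integrated intensity than the cohort median is flagged as a possible
unresolved pair.  Contact is the first frame with the particle boundary
within one pixel of the cell mask; full engulfment is the first frame with
the particle disk entirely inside the mask eroded by one pixel (the
erosion guards against boundary flicker; published assays judged this
visually).  The phagosome signal is the mean R over the in-mask annulus of
0.5 um around the particle — the cup membrane, not the particle disk,
carries the sensor.  In fixed scenes a particle counts as taken up iff it
lies inside a cell mask *and* carries the phagosomal-membrane flag that
distinguishes internalized particles from surface-attached ones.

## The synthetic generator

The generator emulates every quantified scenario with exact ground truth:
a smooth closed outline (ellipse, 15.6 um x 9 um by default — half-length
7.8 um — plus programmed Gaussian protrusion bumps) advected along a
trajectory; an activity field with baseline 1.0, an optional front-high
gradient, a Gaussian peak (sigma 1.5 um) whose axial position runs
front-back-front as a triangle wave, and optional edge-band enrichment;
donor = uniform cell brightness, acceptor = ratio x donor, then optional
affine misalignment of the acceptor, Poisson photon noise and Gaussian
read noise (EM-CCD approximation).  Defaults: 0.27 um/px (nominal for a
60x objective on a 16 um-pixel camera; always configurable), 1 s or 5 s
frame intervals per scenario, 120 s chemotaxis observation, 2 um particles,
10 particles/cell and 15 min incubation for fixed phagocytosis scenes.
Published speed distributions are unavailable, so trajectory speeds
(0.05-0.3 um/s) are chosen for test coverage, not biological fidelity.

What the simulator does *not* emulate: deformable (non-star-shaped) cell
outlines, reaction-diffusion activity dynamics, photobleaching, uneven
illumination, focus drift, or 3D structure (TIRF sees one basal plane).
Passing recovery tests therefore demonstrates the correctness of the
quantification chain, not robustness to every artefact of real data.

## Numerical choices and problem sizes

Noiseless renders are exact (no noise draw), so ratio round-trips are
float-exact; thresholds at printed values are inclusive with a 1e-9 float
guard.  Test and acceptance scenes use 128-160 px frames and <= 150
frames, sizes at which every recovery holds with margin: registration
within 0.02 px (noiseless) and 0.3 px (SNR ~ 10), wave periods T/2 exactly
for T in {8, 12, 16, 20} s, speeds within 5%, turning latency and
engulfment durations within one frame interval.

## Limitations

- Absolute areas and counts differ from manually drawn masks; only
  relative and boundary behaviour is testable against printed thresholds.
- The affine registration cannot correct field-dependent (elastic)
  distortion.
- Protrusion detection assumes star-shaped outlines (radial advance about
  the centroid).
- Group summaries stop at mean/SD/SEM/n (optionally per-experiment
  nested); inferential statistics are intentionally out of scope.
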