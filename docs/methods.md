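# Methods

## The generative model

### Optics and geometry

The simulator emulates a 1-pixel-wide kymograph line over a doubly
tethered lambda DNA (48,502 bp) at 1000 bp/pixel (49 pixels), matching
the conversion used in the velocity formula. The effective per-channel
frame interval defaults to 0.4 s — 200 ms camera integration plus
200 ms shutter delay under alternating three-color acquisition — and is
configurable because the true per-channel cadence of a shuttered
three-color sequence depends on the instrument script. Each fluorophore
contributes a fixed integrated intensity (`unit_intensity`, default
200 counts) spread over pixels by a 1-D Gaussian point-spread function
(sigma 1 px, integrated over pixel bins); pixel *p* covers
[*p*·1000, (*p*+1)·1000) bp, 0-based. Camera background is Gaussian
(mean 100, SD 5, clipped at zero). Photobleaching is geometric per
fluorophore per frame and defaults to off, since shuttered illumination
is used precisely to make bleaching negligible over the observation
window; blinking is not modeled.

### Motor trajectories

A presynaptic complex binds at a uniformly random position (or directly
at the homologous site with probability `p_capture_3d` when a target is
configured), picks a direction uniformly, and draws a velocity and a
total travel distance from mixture models. Both observables are
non-negative, so each mixture component is a **zero-truncated normal
whose post-truncation mean and SD equal the configured values** (solved
numerically from the truncated-normal moment equations). This makes the
configured "mean ± SD" literally the moments of the simulated
population, which is what the closed-form oracles in the tests assume.
One caveat: a zero-truncated normal cannot have SD ≥ mean (its
coefficient of variation is below 1), so for the Rad54-alone population
(65 ± 67 bp/s) the solver matches the mean with priority and accepts
the closest attainable SD (~59 bp/s); the truncation parameter
−mu/sigma is capped at 2 to keep sampling well conditioned. Defaults
are the wild-type PSC populations: velocities 114.3 ± 73 and
394 ± 183 bp/s, travel distances 4.1 ± 0.9 and 6.2 ± 1.9 kb, equal
weights.

Motion is stepwise-constant per frame. Pauses start with probability
0.005 per frame (a rate chosen to make pauses present but rare, as they
are in kymographs of processive translocation) and last 2–4 frames.
A motor that completes its drawn travel stops and dwells (geometric,
mean 25 frames) before leaving the DNA. A motor that reaches a tether
point **terminates there by default** (`end_behavior="terminate"`);
elastic reflection is available but, besides being physically
questionable at a tethered end, it cancels net displacement and would
systematically depress endpoint velocities relative to the configured
populations. On homology-carrying DNA a motor sliding across the target
is captured with probability `p_capture_1d` per crossing (capture mode
1D); direct binders at the target are mode 3D. Captured complexes
either stay for the rest of the record or, with probability
`p_transient_release`, leave after a configurable dwell (default 30 s).

### RPA episodes

Each track receives at most one RPA episode (multi-episode recruitment
is out of scope). The association delay after PSC binding is
exponential with median 8.4 s (0.14 min); the bound lifetime is
exponential with mean 150 s, which leaves roughly half of the episodes
still bound at the end of a ~160 s record. The molecule count is drawn
from a discrete maximum-entropy law on 1–6 whose mean and SD are
exactly 2.5 and 1.5 — the least-committal count distribution matching a
reported mean ± SD. Episodes whose drawn dissociation falls after the
last frame at which the track is observable (the PSC left, or the movie
ended) are flagged censored: their dissociation cannot be observed.
Each of the n molecules bleaches independently when bleaching is
enabled. The RPA footprint is 30 nt of ssDNA per heterotrimer, the
value that converts 2–3 molecules into 60–90 nt of strand separation.

### Colony assay

Colony records are generated by inverting the outcome decision tree:
for a requested (outcome, color class) the simulator writes the
color/marker phenotype that the classifier maps back to that outcome,
so classifier∘simulator is the identity by construction — the
round-trip tests then guard the decision tree itself. BIR is only
expressible in sectored colonies (an unsectored colony resistant to
both antibiotics is indistinguishable from NCO), so BIR probability
mass on unsectored classes is rejected rather than silently
misclassified.

## Segmentation

Peaks are per-frame 1-D local maxima above background + SNR·noise
(background = image median, noise = scaled MAD; default SNR 5), refined
by a ±2 px background-subtracted centroid. Detections are linked
greedily by nearest position with a gate of 3 px/frame (covering the
fastest documented velocity at default optics) and up to 2 dark frames;
tracks shorter than 5 frames are dropped as noise. For rule evaluation
the centroid trace is gap-filled, smoothed with a 3-frame median (a
single-frame localization flicker would otherwise break static runs and
shift termination calls), and rounded to whole pixels, because all
thresholds are stated in pixels.

The reading rules: a molecule **has translocated** once its net
displacement from the binding pixel exceeds 2 pixels (`start_frame`
records the frame this criterion is met); interior static runs of 2–4
frames between movement onset and stop are **pauses**; a final static
run longer than 10 frames marks **termination**. Two choices here are
deliberate and load-bearing:

- The termination rule is applied to the final static run only. Applied
  to any static run, it would classify every molecule slower than
  1000 bp / (10 frames · 0.4 s) = 250 bp/s as terminated inside its
  first pixel dwell — contradicting the slow populations the assay
  demonstrably measures.
- The velocity/distance endpoints are **not** taken at `start_frame`.
  Measuring from the frame the >2 px criterion is met discards the
  first ~3 pixels of every track; for the 4-kb travel population that
  removes most of the signal and collapses measured velocities toward
  zero (verified on simulation). Instead the measurement origin is the
  **movement onset** — the first departure from the binding pixel — and
  the stop is the entry into the final pixel. Both endpoints are then
  pixel-entry events, which makes the endpoint slope an unbiased
  estimate of a constant velocity; the endpoint positions themselves
  use the sub-pixel centroid (threshold rules stay pixel-rounded). The
  >10-frame rule decides only whether the molecule terminated at the
  stop or the record simply ended there.

Velocity is `|Yf − Yi| · bp_per_pixel / ((Xf − Xi) · frame_interval)`
with pauses included in the elapsed time, exactly as the endpoint
formula implies; a pause-excluded variant exists but is not the
default. Tracks that never meet the start criterion have no velocity
(they are unmeasurable, and are excluded from population fits) and a
distance of 0. Velocity is invariant to time translation and position
reflection, and distance·1000/elapsed ≡ velocity by construction.

## Population fits

Gaussian mixtures are fit by EM (scikit-learn backend) with one run
initialized from a quantile split of the sorted sample plus nine seeded
random restarts, a variance floor of (10⁻⁶ · sample SD)² against
component collapse, and samples sorted internally so the fit is
order-invariant. Components are reported in increasing order of mean.
Model selection among {gaussian, lognormal, gauss2, gauss3} minimizes
BIC (it penalizes the extra three parameters of a third component and
is reproducible, where a graphing package's default comparison is not), with ties broken toward
fewer parameters. The lognormal is fit with location fixed at zero and
requires positive samples. `summarize` reports mean, unbiased SD
(absent for n = 1), SE, midpoint median and n.

## RPA analysis

An RPA episode is called when a magenta-channel peak lies within 2 px
of a track position for at least 2 consecutive frames (single-frame
coincidences are noise; the 2-frame persistence is the automated
surrogate for scoring colocalization by eye). Association delay is
(assoc − bind) frames converted to seconds; the dissociated fraction is
uncensored events over all events — no decay-rate fit is used, because
censored events make rate estimates window-dependent. An episode still
colocalized at the last frame at which its track is observable is
censored. Global background is the median intensity of pixels more than
4 px from any track: the median of track-free pixels is robust to the
bright minority of occupied pixels and unbiased for Gaussian noise. Event intensity is the median over event frames of the
raw intensity summed in a ±4 px window (capturing >99.99% of the PSF
mass at sigma 1 px); stoichiometry is (intensity − background·window) /
unit_intensity, floored at zero, with the (floor, ceil) quantized range
times the 30 nt footprint giving the underwound-DNA range. The median
over frames, rather than the per-frame maximum, estimates the intensity
plateau without the upward bias a max over noisy frames would add.

## Homology search scoring

Binding profiles are normalized histograms of PSC positions at a
snapshot time (default 900 s) in 1000-bp bins — one bin per pixel,
since positions are pixel-resolved. Enrichment is the target-bin
probability over either the mean off-target bin probability or a
reference profile's probability at the same bin. A track ending within
one bin of the target is an alignment event; it is 1D if its net
translocation before stabilizing exceeds 2 kb and 3D otherwise —
sliding below the resolution cannot be excluded, so short-range capture
is operationally 3D. Transient dwellers are target-aligned molecules
that dwell at least 20 s and then leave; a 10 s threshold is also in
circulation for this quantity, so the cutoff is an explicit argument
rather than a constant.

## Outcome statistics

Per-replicate outcome fractions are computed within a population
(sectored, solid red, or all colonies) over all categories including an
explicit `unclassifiable` residual — real plates contain ambiguous
colonies, and dropping them silently would bias the fractions.
Chromosome loss (failure of the −Ura/−Met segregation control) takes
precedence over marker logic. Replicates with no colonies in the
population are excluded with a warning. Between-strain comparisons use
Welch's two-sided t-test on replicate fractions (robust to unequal
replicate variances, the common case between strains),
with an exact/Monte-Carlo permutation test available as an independent
check — with 6 + 6 replicates the permutation null is nearly exhaustive
and the two agree to within a few hundredths.

## Problem sizes and verification

The recovery harnesses in `curtainkit.recovery` run the entire chain —
simulate → render → segment → analyze — at the documented population
parameters, with binding kept sparse (≲0.6 tracks per DNA, protein
arriving early in the record, as in a curtain injection) so that
trajectory crossings do not corrupt linking. The shipped configurations
use 2000 tracks for the wild-type velocity mixture (the EM fast-mean
estimate has ~4–6% intrinsic sampling spread at a few hundred tracks;
2000 brings it under 3%), 800 tracks over a 1000-s record for the slow
Rad54-alone population, ~300 RPA episodes over a 100-s record, and
6 × 500 sectored colonies. On one CPU the full acceptance run takes
about a minute.

What passing recovery shows — and what it does not: the synthetic data
share the statistical structure of the real observables (mixture
velocities, PSF + Gaussian camera noise, censored exponential
lifetimes, multinomial colony counts) but idealize away stage drift,
uneven illumination, tether failures, overlapping molecules beyond
incidental crossings, aborted binding events, and any sequence-level
effects (the homologous site is a coordinate, not a sequence). Recovery
on this generator validates the estimators and their composition, not
robustness to every artifact of real microscope data.

## Known limitations

- One RPA episode per track; stepwise photobleaching step-counting is
  not implemented (unit intensity is a calibration input).
- Pause annotation inherits pixel-dwell ambiguity: a fast molecule's
  ordinary 2–4-frame pixel dwells are indistinguishable from true
  pauses under the stated rules, so pause lists are conservative
  annotations, not kinetic measurements.
- The endpoint velocity of a molecule that reverses direction
  underestimates its speed; with end-termination as the default this
  affects only mid-track reversals, which the generator does not
  produce.
- Gene-conversion tract length is encoded only through colony color;
  cutting kinetics and induction efficiency are not modeled.
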