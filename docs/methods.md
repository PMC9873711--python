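# Methods

`permeoscope` analyses trajectories of anion channels in a cylindrical pore
frame and ships a synthetic gated-pore generator whose ground-truth ledger
makes every estimator testable at desk scale.  This note records the models,
conventions, numerical choices and their limitations.

## Pore coordinate system

The coordinate frame is right-handed with z along the membrane normal and
the extracellular side at +z.  All frames are rigidly superposed (Kabsch,
SVD with reflection exclusion) onto frame 0 on the Cα atoms of the annotated
transmembrane helices.  The axial origin is the Cα of a designated origin
residue (T338 for CFTR), re-read **every frame** so the origin tracks
residual protein drift; all reported z values are origin-relative.

The pore is a cylinder determined per frame: pore-helix Cα atoms with
origin-relative z in (−40, 20) Å are selected; the cylinder centre is their
unweighted xy mean ("centre of mass" of identical Cα masses) and the radius
the mean xy distance from that centre.  A flag can freeze the frame-0
cylinder if a fixed reference is preferred; the default recomputes because
helix drift of a few Å is common on the microsecond scale.

## Ion traces and permeation counting

An ion is *inside the pore* when its xy distance to the cylinder centre is
below the radius and −40 < z < 20 Å.  Ion z is unwrapped by minimum-image
accumulation (a frame-to-frame jump larger than half the box height is a
passage through the periodic boundary).

Permeation events use two committor planes at z = −20 and +10 Å, bracketing
the hydrophobic bottleneck (−5 < z < 5 Å) widely enough that ions which
merely visit the bottleneck entrance are not counted: an event is a passage
from below the lower plane to above the upper plane (or the reverse)
without touching the far side in between.  The detector is wrap-aware, so a
boundary re-entry re-arms the machine instead of fabricating a return
passage.  Both planes are configurable.  Bursts are single-linkage clusters
of event times with a 100 ns gap threshold.

Exit pathways are assigned at the first frame of an event with z > +2.5 Å
(the upper bottleneck, where the routes diverge) from the ion's xy bearing
about the cylinder centre relative to four anchor Cα atoms at the
extracellular helix ends (for CFTR: I106/TM1, R334/TM6, Y914/TM8,
I1131/TM12).  The two nearest anchors name the gap — {TM1,TM6} → "1-6",
{TM1,TM12} → "1-12" — a nearest anchor on TM8, or a sector call whose
second/third-nearest margin is under 10°, gives "intermediate"; anything
else is "unassigned".  The bounding-helix description of the routes is
qualitative in the source structures, so the sector rule is this package's
own construction; it is validated on constructed exits with known labels.

## First solvation shell

A molecule or residue is a first-shell partner of an ion when **any** of its
atoms lies within the contact cutoff.  For all-atom systems the cutoff is
3.0 Å (the nearest contacting atoms are typically hydrogens); for the
hydrogen-free single-site pseudo-waters of the generator the documented
equivalent is 3.5 Å.  Waters count once per molecule; non-water, non-ion
residues count as protein; ion–ion contacts are tallied separately and are
excluded from the protein term.  Solvation profiles bin ion-frames by z
(default 1 Å bins), report water/protein/total means (total = water +
protein exactly), per-residue contributions for tagged residues, and the
*bottleneck hydration deficit*: the vestibule-minus-bottleneck difference in
mean first-shell water count, with a block-bootstrap CI.  Empty bins are
NaN, never zero.

Radial distribution functions use shell-volume and mean-density
normalisation under minimum image, excluding self pairs; `r_max` must stay
below half the smallest box length.

## Hydrophobic-gate wetting

Bottleneck hydration is the count of water oxygens inside the pore cylinder
with −5 < z < 5 Å.  Wet/dry labels come from a threshold; `auto` splits the
counts by 1-D 2-means and uses the midpoint of the cluster means, falling
back (with a warning) to the median when the series is unimodal — a cleanly
two-level series separates its cluster means by ≥ 3 within-cluster spreads,
a unimodal one split at its mean by about 2.7.  Dwell-time statistics are
computed on median-filtered labels (window 3 frames) so single-frame count
fluctuations do not fragment long episodes; raw labels are returned
unfiltered.

SASA uses a native Shrake–Rupley implementation with a deterministic
Fibonacci-sphere point set (default 960 points, probe 1.4 Å, Bondi radii) —
quadrature error ~2% per atom, ~0.3% on residue sums.  Only protein atoms
occlude; solvent and ions are excluded from the occluder set by
`sasa_series`.

The wetting–permeation association reports the fraction of events whose
exit frame is wet and the odds ratio of events in wet vs dry frames.  The
null distribution comes from circular time shifts of the label series
(≥1000 shifts), which preserve both marginals and the gate's
autocorrelation; frame shuffling would not.

## Helix and sidechain geometry

Interhelical distances are Cα–Cα distances between anchor pairs (d_1-6,
d_1-8, d_1-12).  Helix-end xy distributions are 2-D histograms of anchor Cα
positions with an RMS radial dispersion.  Sidechain charge centres follow
the usual convention — Lys: NZ; Arg: unweighted centroid of NE/CZ/NH1/NH2 —
config-overridable, since atom-level definitions vary across studies.  The
dunking analysis pairs the charge-centre z of the tracking sidechain with
the highest in-pore ion strictly below it; frames without such an ion enter
only the marginal, and the dunked-state fraction uses a reported threshold
(default z < +2 Å) chosen so the full marginal is always available alongside.

## Statistics

Percentile bootstrap throughout, default 1000 resamples, 99% level,
deterministic under a fixed seed.  Autocorrelated per-frame series are
resampled in blocks (whole runs when several runs are supplied, contiguous
50-frame blocks otherwise); scalar i.i.d.-like samples are resampled per
element.  Empirical coverage of the 99% interval on Bernoulli means at
n = 10⁴ is ~0.99.

## The synthetic generator

The generator emulates the statistical structure of microsecond MD of a
voltage-gated anion pore, not its physics.  Energies are in kT (kT = 1);
voltage enters only as a linear tilt of the 1-D axial potential.

* **Scaffold** — six ideal poly-alanine-like helices (Cα every 1.5 Å in z)
  on a hexagon of circumradius 10 Å spanning z ∈ [−40, 20], with tagged
  residues at channel-consistent positions (origin Cα at z = 0, binding-site
  residues at the well centres, anchors at the extracellular ends) and
  charged pseudo-sidechains (NZ / guanidinium clusters).  Helices listed in
  `scaffold.drift` drift radially as a slow sinusoid ramping towards their
  extracellular ends (defaults: TM1 2.5 Å, TM6 1.0 Å, period 600 ns),
  emulating the helix-end fluctuations that accompany pore opening.
* **Binding sites as capture grids** — each binding site's residues carry a
  flat hexagonal grid of pseudo-atoms (1.2 Å spacing) spanning the pore disc
  at the well-centre plane.  Ion xy is white noise, so a single site atom
  would make contact-based residence xy-noise dominated; the grid reduces
  the 3.5 Å contact rule to an axial capture band of half-width ≈ 3.47 Å,
  making residence a property of the axial dynamics alone.
* **Gate** — a two-state continuous-time Markov (telegraph) process with
  exact exponential waiting times stands in for wetting transitions
  (defaults k_wet = 0.004/ns, k_dry = 0.01/ns under voltage; the no-field
  condition uses k_wet = 10⁻⁴/ns, emulating field-induced wetting: without
  the field the bottleneck essentially never hydrates).
* **Ions** — independent overdamped Langevin walkers (Euler–Maruyama) on
  U(z) = Gaussian wells (site 1: z = −28, 4 kT, σ 3 Å; site 2: z = −12,
  3 kT, σ 3 Å) + a central Gaussian barrier whose height switches with the
  gate (12 kT dry / 3 kT wet, σ 3 Å) + tilt·z (default −0.08 kT/Å under
  voltage).  D = 10 Å²/ns; substeps keep the diffusive displacement
  ≤ 0.5 Å.  The intracellular wall reflects; the extracellular boundary
  absorbs and re-injects near the entrance, making the permeation flux
  countable and stationary.  Absorbed ions are held at the boundary until
  the end of the frame interval so every completed crossing is visible at
  frame resolution.  Discrete-time absorption misses sub-step crossings, so
  the absorbing plane carries the standard Mannella boundary-shift
  correction (0.5826·√(2 D δt) inside the nominal plane); without it,
  first-passage times at the default substep are biased ≈ +25%.
  These defaults place the conductive regime where the emulated study sits:
  a wet episode of ~100 ns carries a burst of a few translocations, dry
  periods carry none, and whole runs without a wetting episode occur.
* **Waters** — point pseudo-atoms with an oxygen-like radius.  Bottleneck
  waters are Poisson with state-dependent mean (5 dry / 30 wet); a fixed
  bath fills the pore outside the bottleneck; first-shell waters are placed
  on a 2.6 ± 0.25 Å shell around each in-pore ion with mean 6.0 in the
  vestibule and 4.8 in the bottleneck — the programmed partial-dehydration
  signal of 1.2 waters.  Bath and bottleneck waters keep a 4.5 Å exclusion
  from every ion, and a shell water of one ion is re-drawn if it falls
  within the cutoff of another, so each measured shell count equals the
  count drawn for its ion.  Waters carry no identity across frames.
* **Truth ledger** — gate states and transitions, every plane crossing
  (recorded at the emitted frame resolution by an internal wrap-aware
  hysteresis routine, with the substep-level absorption count kept
  alongside), binding intervals per site (axial capture band), and the net
  permeation count.

Everything is reproducible bit-for-bit from (config, seed).

### Purpose-built presets

* `equilibrium()` — stationarity checks.  A wide ensemble (250 000 walkers,
  4 frames 10 ns apart) initialised from the exact Boltzmann law, closed
  reflecting domain, no tilt, shallow wide wells (≤ 2 kT, σ ≥ 3.5 Å) and a
  0.2 Å substep so that both the within-walker correlation of bin counts
  and the Euler–Maruyama stationary-density bias stay below the resolution
  of a million-sample χ² histogram test.
* `single_well()` — residence-time recovery as a clean first-passage
  experiment.  The domain is a sliver around one well (reflecting wall just
  below it at z = −30.5, absorbing boundary just above the capture band at
  z = −24), re-injection lands near the well bottom after a 4-frame parking
  delay (so consecutive binding intervals can never be gap-bridged
  together), and a 0.25 Å substep keeps the first-passage discretisation
  bias ≈ 1%.  Under this geometry a contact-rule binding interval *is* the
  first-passage time from the re-entry point to the absorbing plane, and
  the oracle is the reflecting→absorbing MFPT quadrature
  τ(x) = (1/D)∫ₓᵇ e^{U(y)} ∫ₐʸ e^{−U(s)} ds dy averaged over the re-entry
  window.  The default depth (5.9 kT, σ 2 Å) gives τ ≈ 30 ns, the centre of
  the tens-of-ns regime binding-site residence occupies.

## Binding residence

A binding interval is a maximal run of frames in which the ion contacts at
least one site residue, bridging interruptions up to `gap_tolerance`
(default 1 ns; the underlying study's exact rule is not public, so the
tolerance is exposed and reported).  Durations count frames inclusively
((stop − start + 1)·dt).  Site occupancy is the fraction of frames with at
least one bound ion, a per-frame definition.

A caveat established while designing the recovery test: in a *recurrent*
domain, contact-dwell with gap bridging systematically exceeds the
well-to-band-edge MFPT, because a diffusing ion touching the band edge
re-enters within the tolerance almost surely (we measured factors of ~25
in a closed sliver domain).  Dwell-vs-Kramers comparisons are therefore
only meaningful under the `single_well` first-passage geometry above; on
generic runs the residence numbers are descriptive statistics of the
chosen contact rule, not barrier-escape times.

## Problem sizes

Default analyses run on 800–1500-frame trajectories (0.8–1.5 μs at 1 ns
sampling) with 8 ions and ~500 scaffold + ~500 water pseudo-atoms; the
stationarity check uses 10⁶ ion-frames and the residence recovery ~10³
first-passage events.  These sizes put every statistical check well past
its resolution requirement while a full test run stays in the minutes
range on one CPU.

## What the generator does not emulate

Ion xy positions are white noise in the pore disc (no lateral dynamics, so
exit-pathway labels on generator ions are isotropic; the pathway classifier
is validated on constructed exits instead).  Ions are independent walkers —
no ion–ion correlation, knock-on or electrostatics.  Waters have no
identity, dynamics or hydrogen structure; SASA–wetting coupling is not
programmed (gate-residue SASA varies only through helix drift and sidechain
dunking).  The voltage tilt is not mapped to physical mV — the
field-to-voltage relation (E·L_z, e.g. 32 mV/nm × 16.5 nm ≈ −528 ≈ −500 mV
hyperpolarising) is implemented separately as the documented unit
conversion.  Passing tests therefore certify the estimators against
controlled statistical structure, not any force-field-level realism.
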