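# Methods

## Subunit-poisoning model

Hexamers assembled from a mixture of active and Walker-B-dead protomers at
mutant fraction r are assumed to incorporate either species with equal
probability per slot, so the dead-protomer count k per complex is
Binomial(6, r). A dead protomer is taken to inactivate both of its
nucleotide sites at once (the doping construct carries the Walker-B mutation
in both AAA+ domains), so the threshold m counts protomers, not sites.
Complexes below the threshold run at the fraction of functional sites
(6 - k)/6; at or above it they are fully inactive. The uncoupled
(independent-sites) model is encoded as m = 7 rather than a separate code
path, because extending the threshold sum over all j collapses the activity
to exactly 1 - r.

Activities are always reported normalized to the all-wild-type rate;
absolute rates exist only inside the simulator and the assay layer. The
normalization convention for data is the per-dataset mean of the r = 0
group, since doping experiments measure their own undoped reference.

The closed form is verified against a brute-force oracle that enumerates all
2^6 labeled configurations; the oracle refuses rings larger than 20
protomers rather than silently truncating.

## Hand-over-hand simulator

State is one staircase rank per protomer (ranks 0..4 grip the substrate top
to bottom, rank 5 is the seam, which does not contact substrate). One
productive transition advances every rank by one: the seam protomer rebinds
ATP and re-engages at the top while the bottom protomer releases and becomes
the new seam. Each transition translocates 13 Å / 2 residues and hydrolyzes
`atp_per_step` ATP (default 2, one per AAA+ ring, since the two rings move
in unison; normalized activities are invariant to this choice). Both rings
are modeled as a single coupled staircase.

Design choices where the mechanism is underdetermined:

- **Which defect stalls the cycle.** The only mechanistically mandated
  nucleotide event is ATP rebinding by the seam protomer, so a transition
  requires the current seam protomer to be active; a dead protomer blocks
  the cycle when it reaches the seam. With one dead protomer any placement
  rule yields the same (1-r)^6 ensemble limit.
- **Waiting times** are exponential with one lumped rate (hydrolysis and
  ADP release are not resolved as separate substeps). With `atp_conc` and
  `K_bind` set, the rate is k_step·c/(K+c) — single-site binding, which is
  why simulated ensembles show Michaelis-Menten kinetics with Hill
  coefficient ≈ 1.
- **Stall timing.** A stalled complex is discovered by one further
  exponential wait at the transition rate (the futile ATP-rebinding attempt)
  before the stall event is logged and the escape clock starts; no ATP is
  consumed while stalled or disengaged.
- **Escape semantics.** A stalled complex releases its substrate at rate
  `k_escape`, waits at rate `k_reengage`, and re-engages a *fresh* substrate
  with a uniformly random seam phase. Whether a real complex can resume a
  partially unfolded substrate is unknown; discarding progress is the
  conservative choice and only affects throughput, not ATPase, accounting.
- **Throughput.** A substrate counts as unfolded when translocated residues
  reach `substrate_length`; initial resistance of the folded domain is not
  modeled.

The event loop draws runs of productive transitions as vectorized chunks of
exponential waits — legitimate because the number of transitions until a
dead protomer reaches the seam is fixed by the phase — and is
bit-reproducible for a fixed seed. Ensemble activities are normalized
against an all-active reference ensemble simulated with the same
per-complex random substreams (common random numbers), so r = 0 gives
exactly 1 and doped-vs-reference standard errors are computed from paired
differences.

## Synthetic data

Generators are pure functions of (parameters, seed). Defaults mirror the
assay designs: triplicate activity measurements with additive Gaussian noise
(SD 0.02 on the normalized scale in recovery studies), an r grid of
0–0.9 in steps of 0.1, first-order fluorescence decay
F(t) = F_bg + F0·exp(-k_unf t) (the chaperonin trap prevents refolding, so
only the initial slope is used and the tail shape is immaterial),
first-order band-intensity decay with a flat control condition, and
pore-loop sets with five gripping protomers on an ideal helix
(rise 13 Å, twist 60°, radius 14 Å) plus a seam protomer displaced outward
by 8 Å and up by 6.5 Å. An optional finite-assembly mode replaces the
analytic mean activity with the mean over `n_assembled` binomially sampled
complexes, emulating finite-protein mixing noise; analytic mode is the
default for oracle tests.

What the generators do *not* emulate — plate-reader drift and
photobleaching, gel densitometry artifacts, biased (non-binomial) assembly,
inter-ring asymmetric mutants — bounds what passing tests show: recovery
results demonstrate correctness of the estimators under the stated noise
model, not robustness to instrument systematics.

## Assay reduction and model selection

Initial slopes are ordinary least-squares over the leading window (default:
the larger of 5 points and 10% of the trace); recovery to within 5% requires
k_unf·t_window ≲ 0.1 so the exponential is locally linear. Threshold-model
selection is by residual sum of squares: each m is a parameter-free discrete
hypothesis, so no information criterion is needed and ties break toward
smaller m; bootstrap resampling of replicates within each r quantifies
selection confidence. Fits are unweighted by default. Escape-rate fitting
is a grid search over `k_escape` with common random numbers across grid
points (the seed stream depends on r but not on k), which makes the
stochastic objective quasi-deterministic; the full objective profile is
returned so flatness is visible. Degradation rates come from log-linear
least squares on intensities normalized to t = 0, with the regression
standard error.

## Geometry

The helix fit least-squares a 9-parameter helix model (axis orientation,
center, radius, rise, twist, phase) to pore-loop points taken in cyclic
protomer order, initialized from the cross products of consecutive chords
and refined to machine precision; the seam is the single protomer whose
leave-one-out exclusion minimizes the rms residual, matching its structural
definition as the protomer off the gripping helix. Aperture is defined as
twice the minimal radial distance from the pore axis — the widest cylinder
passing through the opening; published "across" distances may use other
conventions, so compare like with like. Pore tilt is the angle between the
ring-centroid displacement and the mean least-squares ring normal. The
first layer line of a filament is 1/pitch; the measured value is the first
local maximum of the axial power spectrum at ≥10% of the strongest
off-origin peak (a guard against noise ripples), accurate to one FFT bin.

All geometry measurements are rigid-motion invariant; degenerate inputs
(collinear rings, coincident centroids, constant profiles) raise errors
rather than returning numbers.

## Problem sizes and tolerances

Stochastic checks use sizes chosen so Monte-Carlo error is small against
the effect being measured: ensemble-vs-closed-form comparisons use 2000
complexes over 300 time units (3-SE agreement; the finite-horizon bias from
pre-stall transitions is an order of magnitude below the SE), escape
monotonicity 400 complexes over 150 time units on a 5-point rate grid with
paired seeds, threshold recovery 100 seeded datasets per truth, Hill fits
50 replicates of 1000 time units per concentration on a 6-point grid
spanning K_bind, and geometry/assay recovery studies 50–100 seeds.
Closed-form identities are asserted to 1e-12 and exact round trips to 1e-9.

## Known limitations

No force-dependent stepping, substrate secondary structure or unfolding
energetics; no protease docking; no modeling of partial per-site poisoning
or biased assembly; nucleotide occupancy of the empty seam-adjacent sites is
tracked only implicitly through the cycle phase. The Å-per-residue ratio of
the default step (13 Å / 2 residues) is larger than a fully extended chain
would give; the two step sizes are therefore independent parameters rather
than being derived from one another.
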