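# Methods

This note documents the models behind the `isochron` simulator and
estimators: what is assumed, which parameters matter, and what passing the
test suite does and does not establish about real annotation data.

## Data model and units

Skeletons are rooted trees of 3D nodes (position, radius, compartment
label) in the seven-column SWC dialect; type codes map 1→soma, 2→axon,
3→basal dendrite, 4→apical dendrite, and 5 (repurposed) →filopodium, with
unknown codes falling back to a configurable default. Annotations
(synapses, filopodia, mitochondria) are flat CSV rows referencing skeleton
nodes; a dataset bundle is a directory of SWC + CSVs + JSON metadata.

Units are fixed: µm for coordinates, radii and cable lengths; nm² for PSD
areas; nm³ for mitochondrion volumes; the mitochondria coverage unit is
nm² (nm³ per nm of cable), kept in that form so published coverage values
compare directly despite being an unusual unit.

Dendrite "diameter" is 2 × the mean node radius along a fragment. Image
annotators measure diameters across orthogonal views; a skeleton carries
one radius per node, so the mean-radius proxy is the skeleton-native
equivalent, and it describes the shaft only (spines are separate
annotations and never enter the radius).

## Age profiles

An `AgeProfile` fixes one (species, region, layer, age) condition. The
bundled mouse V1 L2/3 (p6, p14, p36, p105, p523) and macaque V1 L2/3 (p7,
p75, p3000) profiles encode the published per-age means for spine density,
somatic synapse and axon counts, axonal synapse/branch frequencies, bouton
volume, neonatal vesicle counts, mitochondria coverage and the basal
coverage–density correlation.

Quantities reported only qualitatively carry defaults chosen once:

- **shaft rates** rise slowly with age (0.064–0.4/µm mouse), consistent
  with a subtle increase of shaft inputs over life;
- **mouse p523 spine rate** is set to 1.5/µm — below the p105 peak of
  2.1/µm, implementing late-life net pruning without a dynamic model (old
  ages reuse printed means where available, e.g. somata);
- **vesicle means** interpolate from the measured neonatal 27.4/bouton to
  an adult 274 (an order of magnitude more, as reported);
- **PSD log-normal parameters**: σ(log) = 0.8 at all ages; the p105 log
  mean exceeds the p14 one by ln(1.665), so the mean junction size grows
  by the reported 66.5%. The absolute scale (e(10.0+0.32) ≈ 30,000 nm² at
  p14) is a plausible PSD area scale, and nothing downstream depends on it
  except the PSD-occupancy bound;
- **excitatory shaft fraction** ≈ 0.24 at every age (0.23/0.26 where
  printed).

## Generators

All randomness flows from one dataset seed through counter-based
`SeedSequence(entropy=seed, spawn_key=(stream, index))` sub-streams, so a
fixed (profile, seed) yields a byte-identical dataset regardless of
generation order.

**Dendrites.** A random-walk polyline with 1 µm steps and exact requested
arc length; radius ~0.8 µm diameter with small node-level jitter. Spine,
shaft and filopodium events are three independent homogeneous Poisson
processes along the cable at the profile rates — the published results are
mean densities, so no clustering structure is assumed. Spine synapse
positions sit ~1.107 µm (sd 0.097) perpendicular to the shaft, matching
the measured spine-to-branch distance scale; shaft synapses sit on the
cable. Each synapse draws a log-normal PSD area, a shifted-Poisson
(≥1) vesicle count, and a bouton radius from a log-normal bouton volume
(σ(log) = 0.4) with the profile mean.

**Somata.** A soma is one node of radius 7 µm. The number of innervating
axons is Poisson(axons/soma mean); each axon contributes 1 + Poisson(λ)
synapses with λ = soma-mean / axon-mean − 1 (clipped at 0), so the
expected total equals the profile's synapses/soma. Only the two margins'
means are published; the compound-Poisson choice is declared, not
inferred.

**Axons.** A tree with b ~ Poisson(branch rate × L) branch points is built
from 2b + 1 equal-length segments so the total cable is exactly L
(default 60 µm); output synapses are Poisson(synapse rate × L), placed
uniformly over the cable, 76% onto spines and the rest onto shafts. Since
the postsynaptic partners lie outside the traced cells, a small stub
skeleton hosts the target nodes. A retraction bulb inflates one terminal
to 3× the base radius and clusters 4 mitochondria on it — deliberately
above the detector's defaults (factor 2.0, ≥3 mitochondria within 2 µm of
the terminal), so planted bulbs are always detectable while radius jitter
(sd 0.03 around 0.3 µm) keeps bulb-free axons far below threshold.

**Shaft partner axons.** Each dendritic shaft synapse is flagged
excitatory with the profile probability and given a traceable 8 µm
presynaptic axon making three further synapses (onto a shared unclassified
target pool), at least one a spine synapse iff the flag is set. The
classification rule then recovers the flagged fraction exactly; sampling
for shaft-composition estimates is restricted to shafts of excitatory
dendrites, which is the measurement's operational definition.

**Mitochondria.** Per dendrite, coverage m (nm²) is
`mean + r·σ_m·(s − rate)/σ_s + σ_m·√(1−r²)·ε`, with s the realized spine
density, σ_s = √(rate/L) its Poisson sd, σ_m = 0.25 × mean, and ε standard
normal — so across dendrites E[m] equals the profile mean and corr(m, s)
equals the basal target r (apical dendrites use r = 0). Coverage is
truncated below at 5% of the mean (vanishingly rare at this CV), and the
total volume is split across 1 + Poisson(L/8 µm) instances by a flat
Dirichlet.

**Field-of-view counts.** Detections per FOV are Poisson(density × area);
each detection is independently sub-threshold (<5 vesicles) with a
configurable distractor fraction (default 0), letting the ≥5-vesicle
inclusion rule be exercised.

## Estimators and statistics

Fragment sampling draws start nodes without replacement and extends toward
the tips; at branch points the default `traverse_branch` rule follows the
thicker daughter (`stop_at_branch` is exposed as the alternative — whether
real 10 µm windows crossed branches is unspecified, so both rules exist
and the default is documented). Membership of an annotation in a fragment
is by its assigned node, mirroring annotator assignment, not spatial
proximity; consequently splitting a fragment and pooling counts/lengths
reproduces the whole-fragment density exactly.

SEM is sd/√n with the n−1 sd; for n = 1 it is reported as 0.

The Mann-Whitney U test uses midranks. With a tie-free pooled sample of
≤16 the exact permutation null is enumerated and the two-tailed p doubles
the smaller tail (capped at 1); otherwise the normal approximation with
tie correction and a 0.5 continuity correction is used. The exact branch
is verified against a brute-force enumeration oracle and against an
independent library implementation; the approximation stays within 0.02
of exact p on small samples and its type-I error at α = 0.05 is calibrated
to [0.03, 0.07] in simulation. No multiple-testing correction is applied,
matching the pairwise-adjacent-ages reporting convention.

Pearson's r gets its two-sided p from the t reference with n−2 df; the
log-normal fit is the ML estimate (moments of the logs) with a
D'Agostino–Pearson normality test on the logs as goodness of fit (n ≥ 8).

Bouton surface area and volume use the sphere formulas 4πr² and (4/3)πr³.
PSD occupancy models the soma as a sphere of the soma node's radius; it is
a qualitative bound (occupancy ≪ 10%) rather than a calibrated quantity.

## Problem sizes and determinism

The recovery benchmarks use 200 ten-µm fragments, 500 somata, 300 axons of
60 µm, and 500 boutons — sizes at which a 3-standard-error band is decisive
for every targeted mean while a full run stays in the tens of seconds.
Pipeline runs are deterministic end to end: the manifest (seeds, parameters,
version) suffices to reproduce every output file byte for byte.

## What the synthetic data does not capture

The generator reproduces the first- and second-order structure the
estimators consume (mean rates, declared correlations, log-normal sizes,
determinism), not real anatomy: no spatial clustering of synapses along
dendrites, no soma/neurite geometry beyond polyline trees and spherical
somata, no annotator error model, no partial-volume truncation of cells,
and no time-resolved synapse turnover (old-age profiles encode net
outcomes, not dynamics). Passing the suite therefore demonstrates that the
estimators are unbiased and correctly wired on data with known ground
truth — it does not validate the published biology itself, which requires
the original volumes.

## Known limitations

- The excitatory-axon rule can only ever produce "excitatory" or
  "unclassified"; inhibitory identity is never asserted (the operational
  rule licenses one direction only).
- Mitochondria membership is by host span; a mitochondrion straddling a
  fragment boundary contributes its full volume to its host dendrite (no
  apportioning model).
- Multi-bouton contacts from one axon onto one soma are counted per
  synapse, not merged.
- The exact Mann-Whitney branch requires tie-free data; discrete counts at
  small n fall back to the tie-corrected approximation.
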