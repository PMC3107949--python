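# Methods

This note documents the model implemented in `footmech`: what is
simulated, the assumptions behind each component, the tunable parameters
with their defaults and units, and what the synthetic-anatomy study
design can and cannot show.

## Overview

The foot/ankle complex is modeled as eleven rigid bone units — tibia +
fibula (one unit), talus, calcaneus, navicular, cuboid, the three
cuneiforms merged, and five rays (metatarsal + phalanges merged) —
connected by unilateral articular contacts and a network of tension-only
ligament bands, standing on a rigid ground plane. Mid-stance is a static
problem: a downward axial force on the proximal tibia plus an Achilles
tendon pull, with the proximal tibia restrained to vertical translation
(one generalized coordinate; every other bone unit carries six). The
equilibrium is found by minimizing the total potential energy.

Phalanges are merged into their rays and tibia/fibula into one unit
because none of the reported measures separates them; this reduces the
problem to 61 generalized coordinates for the intact foot.

## Synthetic anatomy

No subject geometry is used. The generator lays out a deterministic
landmark template of a neutrally aligned right foot (default length
250 mm, arch apex ≈ 0.24 of length, forefoot width 90 mm) and adds small
seeded uniform jitter (±0.6 mm) to every landmark, so different seeds are
slightly different feet. Parameters are validated against documented
ranges (length 200–300 mm, arch fraction 0.15–0.35, width 70–110 mm,
neutral hindfoot lean 0–6°). In the neutral pose the six radiographic
angles fall inside normative adult windows (Meary ±5°, pitch 10–25°,
hindfoot 88–96°, etc.); across seeds 0–99 all 100 generated feet satisfy
all windows. A left foot is the exact mirror image; the handedness flag
tells the measurement code which direction is medial.

Bones are landmark frames plus contact primitives, not surface meshes;
convex-hull meshes can be exported for visualization only.

## Articular contacts

Joint surfaces are emulated by unilateral penalty contacts between
landmark-encoded sites. Each contact measures the advance of the distal
bone's site along a facet normal fixed in the proximal bone (the normal
is itself a landmark 1 mm from the site, so osteotomy fragment
transforms carry facet orientation automatically). Penalty energy is
`kp/(e+1)·pen^(e+1)` with default stiffness `kp = 2000 N/mm` and exponent
`e = 1`. Rest gaps are frozen at generation time, so surgically
re-positioned surfaces register as joint load.

Three articulation archetypes are built from four-pad rings whose
normals are splayed toward the joint interior:

* **hinge** (ankle mortise): fore-aft pad splay matches the talar dome
  curvature, so plantar/dorsiflexion about the dome axis is free while
  the side pads' vertical normals resist inversion/eversion;
* **socket** (subtalar facets, transverse tarsal, naviculocuneiform,
  tarsometatarsal, cuboid-side junctions): converging normals emulate a
  congruent concave surface that resists shear and tilt under
  compression. The calcaneocuboid and posterior subtalar pads carry an
  additional alternating azimuthal twist (±25°/±15°) emulating saddle
  congruence that resists torsion;
* **cup** (talonavicular joint, the acetabulum pedis): all pad normals
  converge at the talar head center 8 mm behind the articular ring, so
  the head rotates freely in its socket — joint angulation is owned by
  the ligaments — while subluxation is blocked.

This distribution of articular freedom is the central design decision of
the model: the column joints that the disease deforms (talonavicular
above all) are rotation-free, so staged ligament attenuation can express
as angular deformity rather than being shunted through bony contact.

## Ligaments

Each band is a tension-only linear spring, `T = k·max(0, L − L0)`, with
the path length `L` measured through optional via beads (frictionless
pulley points; bead radius is kept only for mesh export). The plantar
fascia bands wrap beads under the metatarsal heads; the two spring
(calcaneonavicular) bands run from the sustentaculum over a bead on the
plantar-medial talar head to the navicular — the hammock on which the
talar head rests.

Stiffnesses: the ten named structures use the published attenuation
table's values; healthy baselines are back-computed as
`attenuated/(1 − fraction)` (e.g. superomedial spring 39/(1/8) =
312 N/mm). All other bands — four ankle ligaments, the transverse
forefoot ties, the Lisfranc band, and the generated capsule cages — use
the mean of the named baselines (183.9 N/mm), following the convention
of averaging known structures for unreported ones. Every joint carries a
generated "capsule cage" of oblique crossing fibers (four per joint;
eight at the clinically near-immobile naviculocuneiform/tarsometatarsal
row; dorsal-only at the talonavicular joint, whose plantar capsule *is*
the spring complex). The default skeleton carries 121 bands — more than
a minimal set, because the cage fibers provide the rotational stability
that 144 subject-specific bands provide in a cadaver-derived model.

Rest lengths are calibrated from the neutral pose and an in-situ strain
table (`L0 = L_neutral/(1+ε)`), band > group > global resolution, global
default 2 %. Encoded group values: plantar fascia and long plantar 0.2 %,
short plantar and intermetatarsal 0.5 %, superficial deltoid 1 %, spring
complex 3 %. Rationale: with linear springs a 2 % pre-strain over a
200 mm plantar path would carry hundreds of newtons at rest and lift the
toes off the floor, while the spring hammock needs enough pre-tension to
stay recruited through stance (real ligaments achieve both through
toe-region nonlinearity, which this model deliberately omits). These
magnitudes are configuration, not measurements.

## Loads and equilibrium

The load case is 690 N straight down at the proximal tibia landmark and
an Achilles tendon modeled as a constant-tension 345 N cable from the
calcaneal tuberosity to a proximal gastrocnemius/soleus point (slightly
lateral, as in stance). Ground contact spheres under the five ray heads
and the heel produce vertical penalty forces plus a tangential spring
(default 40 N/mm) representing the finite fore-aft/transverse compliance
of foot-ground interaction; a rigid no-slip ground would freeze the arch
chord and suppress arch mechanics entirely, while a frictionless plane
could not react the Achilles couple.

Each scenario is solved in two phases: first the **unloaded equilibrium**
(no external loads, no tangential springs — an unloaded foot re-poses
freely, which is where an osteotomy reshapes the foot), which also
provides the reference lengths for strain reporting; then the **loaded
equilibrium**, ramping the loads in equal increments (default 10) with
warm starts, the tangential springs anchored at the unloaded contact
positions ("anchored at first contact activation"). Each ramp stage is
minimized with L-BFGS-B inside a trust box around the previous solution
(half-width 4 mm, re-centered until interior) — tension-only networks
buckle through unphysical basins if the line search may take arbitrary
steps; the box is inactive at any accepted solution, so it never alters
converged physics. Rotation coordinates are rotation vectors scaled by
50 mm so every coordinate is in millimetres and the gradient is in
newtons; convergence requires gradient norm ≤ 0.5 N (≈0.1 % of body
weight). The analytic gradient is exact (verified against central
differences to 1e-5 relative); the solver contains no randomness, so
identical inputs give bit-identical iterates.

A documented reduced-effort profile (trust box 12 mm, 4 ramp stages) is
used for multi-seed trend studies; spot checks agree with the default
profile to <0.01° on every reported angle.

## Disease model

Stage II flatfoot attenuates band stiffness by the staged fractions
(stage 0: none, I: 1/8, II: 3/8, IV: 7/8; stage III does not occur in the
staging template and is deliberately unrepresentable). Attenuation
applies per structure group (all five fascia bands get −1/8), never
changes geometry or rest lengths, and is single-shot (re-application is
rejected via the band's damage-stage provenance).

## Virtual surgery

All three procedures are rigid transforms of landmark subsets; fragments
re-fuse to their parent body, and every intra-fragment distance is
preserved to 1e-9 mm. Ligament attachments and contact sites are
landmarks, so they ride their fragment — this is how the procedures
re-tension the plantar structures.

* **MCO**: cut plane at 35 % of the tuberosity-to-articular-surface span;
  everything posterior (Achilles insertion, heel contacts, plantar
  fascia origin) translates 10 mm medially.
* **Evans**: cut 10 mm behind the calcaneocuboid articular surface; the
  anterior fragment rotates about a vertical hinge on the medial border
  of the cut by arctan(width/depth) = arctan(10/25) = 21.80°, opening the
  wedge laterally. The wedge is not modeled as material — the fused
  construct is one rigid body; a wedge mesh exists for display only.
* **CCDA**: 3 mm resection of each shared articular surface, the whole
  cuboid rotated by the same hinge angle, then fused into the calcaneal
  group (its contact pairs deactivate; the calcaneocuboid force is
  reported as not applicable).

Combined procedures apply the lateral procedure first, then the MCO;
Evans and CCDA are mutually exclusive.

## Measurements

Angles are read from landmark axes in radiographic projections: lateral
(sagittal) for Meary/talocalcaneal/pitch; an AP view with the viewing
direction raised 70° from horizontal within the sagittal plane for the
AP talo–first-metatarsal and talonavicular coverage angles (medial
deviation positive = adduction); posterior (coronal) for the hindfoot
angle. All are invariant under a global rigid transform applied together
with the reference frame.

Hindfoot sign convention: valgus (eversion) means the heel — the distal
segment — deviates laterally, i.e. the calcaneal bisection line's top
tips *medially*; that reads above 90° on the +90°-shifted scale. This is
the standard clinical reading (as for genu valgum) and it is what makes
a simulated medializing calcaneal osteotomy read as varus correction.

Talonavicular coverage uses the navicular articular chord's in-plane
anterior normal against the talar axis (the chord construction is a
package convention; clinical landmark definitions for this angle vary).
Strain tables report engineering strain relative to the same scenario's
unloaded equilibrium, medial→lateral, eight long plantar and five fascia
bands. Reporting precision: 0.1° / 0.1 % strain / 1 N; all internal
computation is full precision.

## Study design and what it shows

The default study is seven configurations of one foot: normal, flatfoot,
and flatfoot + {MCO, Evans, CCDA, Evans+MCO, CCDA+MCO}. Because the
anatomy is synthetic, absolute values are generator-specific; the
scientific outputs are cross-configuration comparisons, assessed as
direction consistency across anatomy seeds (10 seeds for the trend
suites; 3 seeds × {0.57×, 1.43×} uniform stiffness scaling for
robustness — sizes chosen to keep the full suite to minutes per study).

Simulated disease and correction trends reproduce the clinical pattern
in direction: flatfoot drops the Meary and AP talo–first-metatarsal
angles, everts the hindfoot, and shifts load toward the medial forefoot;
MCO inverts the heel and adducts the forefoot; lateral column
lengthening swings the forefoot into adduction, loads the fifth ray, and
(Evans) roughly doubles calcaneocuboid joint force, which arthrodesis
eliminates. Two caveats are documented rather than hidden:

* **magnitudes are compressed**: simulated disease deltas are tenths of a
  degree versus several degrees in cadaver-derived models. With
  synthetic congruent joints, a larger share of load bypasses the
  attenuated structures than in real anatomy; sign consistency across
  seeds, not magnitude, is the supported claim.
* **medial forefoot unloading under Evans is not robust**: the fused
  wedge reliably loads ray 5, but ray-1 unloading (robust under CCDA) is
  seed-dependent under Evans because the free cuboid transmits the
  lengthening as anterior push more than as forefoot supination.

## Numerical choices and degenerate inputs

Penalty stiffness 2000 N/mm (results verified stable at 0.5× and 2×);
penalty exponent 1 (C1-smooth energy); ramp 10 stages; trust box 4 mm;
tolerance 0.5 N; rotation scale 50 mm; tangential ground stiffness
40 N/mm. Ties and boundaries: a band exactly at its rest length carries
zero force; a contact exactly touching carries zero force; zero-offset
or zero-width osteotomies are exact identities (CCDA still fuses). A
non-finite solver state raises immediately naming the ramp stage;
non-convergence returns a flagged result that the measurement layer
refuses to consume.

With all in-situ strains zero and no loads, the neutral pose is an exact
equilibrium (every force identically zero). With nonzero pre-strain the
unloaded equilibrium settles near, but not at, the neutral pose — a
pre-tensioned tension-only network is not force-free at calibration; the
calibration fixed point is exact only at zero pre-strain.

## Known limitations

Linear (no toe-region) ligaments; no viscoelasticity or rupture; no
posterior tibial tendon or other muscle beyond the Achilles; static
mid-stance only; loads not pressures at the ground (no plantar soft
tissue); bead wrapping ignores bead radius; synthetic anatomy with
merged rays and cuneiforms; the flexor digitorum longus transfer that
accompanies these osteotomies clinically is not simulated.
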