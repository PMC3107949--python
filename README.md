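# footmech

Quasi-static rigid-body simulation of the foot/ankle complex for studying
adult acquired flatfoot deformity (*pes planus*) and its surgical
correction.

The package builds a parametric synthetic foot skeleton (eleven rigid bone
units with named landmarks, articular contacts, and a tension-only
ligament network), loads it in mid-stance (690 N axial tibial load, 345 N
Achilles pull), and solves the static equilibrium by penalized energy
minimization. On top of that base it models:

* **Stage II flatfoot** — attenuation of the medial soft-tissue restraints
  (spring ligament complex, talocalcaneal interosseous ligament, plantar
  fascia, anterior superficial deltoid) by damage-staged stiffness
  fractions (−1/8, −3/8, −7/8);
* **three virtual osteotomies** — medializing calcaneal osteotomy (MCO),
  Evans lateral column lengthening, and calcaneocuboid distraction
  arthrodesis (CCDA), each a rigid landmark-set transform with the
  clinically stated geometry (10 mm medial slide; 10 mm × 25 mm wedge,
  hinge angle arctan(10/25) = 21.8°; 3 mm articular resection + fusion);
* the **radiographic measurement suite** used to grade flatfoot: lateral
  talo–first-metatarsal (Meary) angle, talocalcaneal angle, calcaneal
  pitch, AP talo–first-metatarsal and talonavicular coverage angles, and
  the hindfoot varus/valgus angle (reported on the +90° scale, >90° =
  valgus), plus plantar-band strain arrays, calcaneocuboid joint contact
  force, and per-region plantar ground loads.

Each ligament band is a tension-only linear spring `T = k·max(0, L−L0)`
with optional via beads (pulley wrapping, e.g. the plantar fascia under
the metatarsal heads and the spring-ligament hammock under the talar
head); rest lengths are calibrated from neutral-pose in-situ strains.
Joints are unilateral articular contacts (splayed facet pads emulating
congruent sockets, a cylindrical ankle hinge, a spherical talonavicular
cup) so joint angulation is governed by the ligaments — which is what
lets staged ligament damage express as deformity.

## Worked example

```
python examples/simulate_midstance.py
```

```
converged: True   residual: 0.070 N

loaded radiographic angles (deg):
  l_t1mt        -2.0
  l_tc          30.5
  l_cp          15.3
  ap_t1mt        4.4
  ap_tn        -14.3
  hindfoot      95.3

plantar loads (N):
  ray1            25
  ray2            37
  ray3            41
  ray4            54
  ray5            46
  calcaneus      487
  total          690   (applied axial load: 690 N)

calcaneocuboid joint force: 926 N
```

The residual is the equilibrium force imbalance (solver tolerance 0.5 N).
The plantar loads are the vertical ground reactions under the five rays
and the heel; their sum reproduces the applied 690 N axial load, with
roughly three quarters carried by the heel in mid-stance. A near-zero
Meary angle (`l_t1mt`), calcaneal pitch in the mid-teens and a hindfoot
angle slightly above 90° are normal adult alignment.

Other examples: `examples/generate_anatomy.py` (neutral anatomy),
`examples/compare_surgeries.py` (the seven-configuration disease/surgery
study), `examples/stiffness_sensitivity.py` (±43 % stiffness robustness).

## Command line

A thin CLI wraps the library:

```
footmech generate --seed 0 --out anat/            # skeleton JSON (+ meshes)
footmech run --config suite.yaml --out results/   # scenario suite
footmech compare results/                         # comparison CSV/JSON
footmech export-mesh --skeleton anat/skeleton.json --out meshes/
```

Scenario YAML schema and defaults are documented in
`footmech/interface.py`; runs emit a manifest with configuration and
output checksums for bit-identical re-runs.

## Scope

The synthetic anatomy stands in for subject-specific (CT-derived) bone
geometry, so absolute simulated angles/strains/loads are specific to this
generator; cross-configuration *comparisons* (disease and correction
trends) are the scientific output. See `docs/methods.md` for the model,
its assumptions, parameter tables, and known limitations.
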