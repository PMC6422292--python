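# Methods

## Scope and model idea

`lumbarload` is a planar static musculoskeletal model of upright standing.
It answers one question: how do the sagittal spinopelvic alignment
parameters — sagittal vertical axis (SVA), Roussouly lumbar type (RT),
sacral slope (SS) and pelvic incidence (PI) — shape the intersegmental
loads at the two lowest lumbar levels and the demand on the major trunk
muscle groups?

The body is reduced to rigid segments in the sagittal plane (x anterior,
y up, meters; angles in degrees, flexion positive): a sacrum+pelvis block
(with the leg mass attached below it), the five lumbar vertebrae, one
lumped thorax+ribcage segment, the head, and the arm mass hanging
vertically from the shoulder. Adjacent segments are connected by
frictionless planar hinges at the intervertebral joint centres, so joints
transmit force but no moment; every moment must be balanced by muscle
tension. Disc stiffness, facet contact and ligaments are neglected — in
quiet standing they shift load sharing within a motion segment rather
than the resultant crossing it.

## Posture construction

A posture is one point of the design grid, applied in the order SS, PI,
RT, SVA:

1. **SS** — the sacrum segment stands at a default slope of 30°; the
   target slope is reached by rotating the segment about the L5S1 joint
   by `SS − 30°`. All sacral/pelvic muscle attachment points rotate with
   the segment; the superior endplate inclination then equals SS in the
   world frame.
2. **PI** — with PT = PI − SS, the hip centre is placed at horizontal
   offset `hip_drop · tan(PT)` anterior of the endplate midpoint, at a
   fixed vertical drop. Only the horizontal coordinate moves. Because
   everything above the L5S1 joint is unaffected by the hip position, all
   lumbar outputs are *exactly* invariant in PI — the model reproduces
   the study's null result by construction, which is also the cleanest
   reading of how a hip-only shift can enter a statics problem.
3. **RT** — each lumbar vertebra takes a fixed world-frame inclination
   per type (flexion positive; the tabulated values are mostly
   extensions). The inclinations are world-frame absolutes, not offsets:
   only that reading reproduces the published wedge-angle arithmetic
   (L5−S1 extension spanning −43° to −13°, and a 43° anterior-axis
   divergence for RT1 at SS 35°). Joint centres stack caudally to
   cranially from L5S1 at the origin, each vertebra contributing its
   joint-to-joint height along its own axis. Vertebral centres of mass
   sit anterior of the segment centroids by a per-level offset
   (CT-derived convention, 10–20 mm, increasing caudally).
4. **SVA** — the thorax rotates about T12L1 until the horizontal offset
   from C7 to the posterior-superior corner of the sacral endplate equals
   the target SVA. The root is found by bracketed 1-D root finding
   (Brent) within ±45°; the C7 offset is continuous and strictly monotone
   there, and the solve closes to 10⁻⁶ cm. The head is counter-rotated
   to stay level, and the arms remain plumb below the shoulder.

Lumbar lordosis is reported between T12 and S1:
`LL = SS − (thorax rotation + T12 offset)`.

## Mass and anthropometry

Default body: 1.76 m, 75 kg. Mass fractions follow standard segment
inertia tables, with the lower-trunk fraction split between the five
lumbar vertebrae (1.2 % each) and the pelvis block; the partition must
sum to 1 within 10⁻⁹ or chain assembly refuses. Gravity is 9.81 m/s²
exactly. All lengths, offsets and fractions live in `defaults.toml` and
can be overridden from a user TOML file; absolute Newton outputs depend
on them, the geometric alignment quantities do not.

The trunk COM sits 7.2 cm anterior of the T12L1–C7 chord. This is the
single most load-bearing constant: it sets the flexion-moment baseline
that keeps the balanced and frontward postures extensor-dominated
(rectus abdominis silent) while leaving the backward postures
flexor-demanding. The value is consistent with the trunk mass centroid
lying mid-chest, well anterior of the spinal column.

## Muscles

The trunk musculature is lumped into seven bilateral-summed straight-line
actuators:

| group | path | role |
|---|---|---|
| multifidus ×5 | spinous-process point of each vertebra to the next (L5 to sacrum), 5.5 cm posterior lever | mono-segmental extensors, one per lumbar joint |
| erector spinae / longissimus | lower thorax (9 cm posterior) to posterior iliac crest | global extensor crossing all lumbar joints |
| rectus abdominis | costal cartilage (11.5 cm anterior) to pubic crest | global flexor crossing all lumbar joints |

Mono-segmental multifidus fascicles are a deliberate reduction: they
guarantee that every gravity-moment profile the grid can produce is
balanceable with nonnegative tensions (each joint owns a dedicated
extensor, and one global flexor can always lift the most
extension-demanding joint to feasibility). Literature reports both mono-
and poly-segmental deep multifidus fibres; the mono-segmental choice
trades some anatomical nuance for unconditional solvability across all
2772 configurations.

Moment arms are signed perpendicular distances from the joint centre to
the straight line of action, positive when tension extends. The
"longissimus spinae" and "erector spinae" names refer to the same
actuator and its force is reported under both (`f_es`, `f_ls`).

Abdominal pressure exists as an optional stub (a uniform extension
moment at every lumbar joint, proportional to a configured pressure,
diaphragm area and lever); it is off by default and all reported
behaviour assumes it off.

## Recruitment

For each posture the net flexion-positive gravity moment of the
superincumbent body is assembled at the five lumbar joints L1L2…L5S1,
and muscle tensions solve

minimize Σᵢ (fᵢ/Sᵢ)³  subject to  Σᵢ arm[j,i]·fᵢ = M_g[j],  fᵢ ≥ 0,

the cubic polynomial activation criterion (power exposed as a config
knob; convex and uniquely minimized in activations for any power > 1).
The thoracolumbar junction (T12L1) is excluded from the constraint set:
with a lumped seven-actuator set only the two long actuators cross it,
which would over-constrain the problem, and thoracolumbar load artefacts
of the lumped-thorax idealization are outside this model's scope.

Numerically, a linear program finds a feasible starting point (and
certifies feasibility), SLSQP minimizes in activation variables, and a
least-norm projection restores the equality constraints to machine
precision. The contract is a moment residual ≤ 10⁻⁶ N·m on every
configuration; violations raise rather than degrade. Activations above 1
warn but are not capped — the default grid never saturates.

Intersegmental force at a level is the free-body resultant transmitted
to the element below: superincumbent gravity plus the tensions of
crossing fascicles pulling toward their caudal attachments. In standing
this points downward; projected on the level's axes it yields positive
compression.

## Load decomposition

At L4L5 the axial (compression) direction runs from the L4L5 joint to
the L5S1 joint — caudally along L5 — and the anterior (shear) direction
is its +90° orthogonal, parallel to the L5 upper endplate. At L5S1 the
anterior direction is parallel to the sacral endplate at the
configuration's SS and the axial direction is its caudal normal. The two
frames are each exactly orthonormal; the tabulated L5 inclination and
the endplate-parallel wording coincide only approximately in general,
and orthogonality is the enforced reading. Compression and shear are the
projections of the transmitted force; ‖F‖² = c² + s² holds to 10⁻⁹
relative.

## The sweep

Per type, SS and PI run over their closed published ranges in 1°
increments (11 × 21 points) under three SVA conditions, giving
4 × 11 × 21 × 3 = 2772 configurations. Results are collected long-form
(one CSV row per configuration) and aggregated as median and min–max per
(output, type, SVA) over the SS × PI grid; an even-count cell's median
is the midpoint of the two central order statistics. The sweep is
deterministic and runs in well under a minute on one CPU.

## What the emergent behaviour shows — and does not

With the default constants the model reproduces, as emergent behaviour
rather than anything hard-coded:

- exact PI-invariance of every output;
- rectus abdominis silent in all frontward and (for RT1–RT3) balanced
  postures, active in every backward posture;
- erector spinae demand ordered frontward > balanced > backward;
- higher L4L5 compression frontward than balanced, everywhere;
- at the central PI, steeper sacral slope lowering L4L5 shear and
  raising L5S1 shear in every type and SVA condition.

Absolute Newton values are of the right magnitude (hundreds of N of
compression) but are *not* calibration targets: they depend on the
editable anthropometric and attachment constants, and full-fascicle
musculoskeletal models against which one might compare them use
proprietary geometry. Two qualitative departures from such models are
known and accepted: the lumped set routes more extensor demand through
the segmental multifidus (and less through the erector spinae) than a
many-fascicle recruitment does, and in backward and RT4-balanced
postures the long extensor is exactly silent here where many-fascicle
models with abdominal pressure retain a small residual extensor force —
both consequences of having a single global flexor–extensor pair
instead of hundreds of fascicles.

## Robustness and its limits

The sampling module jitters every length, mass and attachment offset by
independent factors in [1−j, 1+j] (mass fractions renormalized). At
j = 0.1 the qualitative findings above hold across the fixed 20-seed
panel used in the acceptance suite. The sacral-slope shear trends are
the tightest of these properties: in RT4 — where the pelvic rotation is
largest and the gravity moments at the mid-lumbar joints are near zero —
the SS_min/SS_max shear difference is only a few newtons, and
sufficiently adverse attachment perturbations can invert it. That
fragility is physical, not numerical: the trend is a small difference of
large, oppositely-moving muscle contributions.

## Synthetic inputs

There is no external data; the published table of healthy spinopelvic
parameter ranges and per-type vertebral inclinations *is* the input. The sampler draws valid (RT, SS, PI, SVA) tuples
on the same integer-degree grid the sweep uses, which is what the
analysis assumes about real measurements (integer-degree radiographic
readings within published physiological ranges). It does not model the
real-population interdependence between parameters (e.g. frontward
imbalance co-occurring with particular slopes); the grid deliberately
explores all combinations, including rare ones.

## Parameter summary

| constant | default | units | meaning |
|---|---|---|---|
| `default_ss_deg` | 30 | ° | slope of the unrotated sacrum |
| `sacral_endplate_width_m` | 0.05 | m | AP diameter of the S1 endplate (SVA reference corner) |
| `hip_drop_m` | 0.09 | m | endplate midpoint to hip axis, vertical |
| `thorax_length_m` | 0.29 | m | T12L1 to C7 |
| `thorax_com_local_m` | (0.072, 0.15) | m | trunk COM in the thorax frame |
| `vertebra_heights_m` | 0.036–0.038 | m | joint-to-joint lumbar heights |
| `com_anterior_offsets_m` | 0.010–0.020 | m | vertebral COM anterior of centroid |
| `criterion_power` | 3 | – | recruitment polynomial power |
| `residual_tol_nm` | 1e-6 | N·m | equilibrium contract |
| muscle strengths | 650 / 2200 / 900 | N | multifidus (each) / erector spinae / rectus abdominis |
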