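# Default model constants.
#
# Geometry is a 2-D sagittal-plane skeleton scaled to a 1.76 m / 75 kg adult
# male. Lengths in meters, masses in kg, angles in degrees (flexion positive),
# forces in N. Joint-to-joint distances and attachment offsets are
# stature-scaled conventions; absolute force outputs depend on them, the exact
# geometric alignment quantities do not.

[posture]
default_ss_deg = 30.0          # sacral slope of the unrotated sacrum segment
sacral_endplate_width_m = 0.05 # anteroposterior diameter of the S1 endplate
hip_drop_m = 0.09              # vertical drop, endplate midpoint -> hip axis
t12_offset_deg = 0.0           # T12 upper-endplate tilt relative to the thorax segment
thoracic_bracket_deg = 45.0    # search bracket for the thoracic rotation solve

[anthropometry]
stature_m = 1.76
mass_kg = 75.0
gravity_m_s2 = 9.81
thorax_length_m = 0.29             # T12L1 joint to C7 marker
thorax_com_local_m = [0.072, 0.15] # chest/abdomen mass sits anterior to the column
shoulder_local_m = [0.0, 0.26]
head_com_offset_m = [0.01, 0.09]   # from C7, world frame (head stays level)
arm_com_drop_m = 0.25              # arms hang vertically below the shoulder
pelvis_com_offset_m = [0.0, -0.30] # pelvis+legs lumped mass, below the sacrum

# Joint-to-joint height of each lumbar vertebra (body + disc).
[anthropometry.vertebra_heights_m]
l1 = 0.036
l2 = 0.037
l3 = 0.038
l4 = 0.037
l5 = 0.036

# Anterior offset of each vertebral centre of mass from the geometric
# centroid (CT-based convention; increases caudally).
[anthropometry.com_anterior_offsets_m]
l1 = 0.010
l2 = 0.012
l3 = 0.015
l4 = 0.018
l5 = 0.020

# Whole-body mass partition; must sum to 1.
[anthropometry.mass_fractions]
sacrum_pelvis = 0.4489  # pelvis plus both legs (below the L5S1 joint)
l1 = 0.012
l2 = 0.012
l3 = 0.012
l4 = 0.012
l5 = 0.012
thorax = 0.3229
head = 0.0694
arms = 0.0988

[solver]
criterion_power = 3.0
residual_tol_nm = 1e-6

# Lumped bilateral actuators. Local attachment coordinates are expressed in
# the owning segment's frame (origin at the segment's caudal joint; for the
# sacrum, at the endplate midpoint).
# Multifidus: mono-segmental fascicles at the spinous-process lever arm.
[muscles.multifidus]
posterior_offset_m = 0.055
sacrum_local_m = [-0.045, -0.020]
strength_n = 650.0

# Erector spinae / longissimus: lower thorax to the posterior iliac crest.
[muscles.erector_spinae]
thorax_local_m = [-0.090, 0.020]
sacrum_local_m = [-0.080, -0.185]
strength_n = 2200.0

# Rectus abdominis: costal cartilage to the pubic crest.
[muscles.rectus_abdominis]
thorax_local_m = [0.115, 0.060]
sacrum_local_m = [0.110, -0.085]
strength_n = 900.0

[muscles.abdominal_pressure]
enabled = false
pressure_kpa = 0.0
diaphragm_area_m2 = 0.0045
moment_arm_m = 0.048

# Spinopelvic parameter ranges and fixed world-frame vertebral inclinations
# for the four Roussouly lumbar types (flexion positive). SVA in cm.
[table1.RT1]
ss_range_deg = [25, 35]
pi_range_deg = [30, 50]
sva_cm = { back = -3.0, med = 3.0, front = 9.0 }
vertebral_rotation_deg = [-17.0, -22.0, -27.0, -19.0, -8.0] # L1..L5

[table1.RT2]
ss_range_deg = [25, 35]
pi_range_deg = [30, 50]
sva_cm = { back = -4.9, med = 1.1, front = 7.1 }
vertebral_rotation_deg = [-12.0, -13.0, -8.0, -1.0, 9.0]

[table1.RT3]
ss_range_deg = [35, 45]
pi_range_deg = [40, 60]
sva_cm = { back = -4.5, med = 1.5, front = 7.5 }
vertebral_rotation_deg = [-20.0, -22.0, -12.0, -2.0, 22.0]

[table1.RT4]
ss_range_deg = [45, 55]
pi_range_deg = [50, 70]
sva_cm = { back = -6.3, med = -0.3, front = 6.3 }
vertebral_rotation_deg = [-20.0, -14.0, -2.0, 9.0, 30.0]
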