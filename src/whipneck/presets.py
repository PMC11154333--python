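"""Built-in parameter presets for the planar head-neck chain.

All values are stored exactly as published for the 50th-percentile male
occupant geometry: lengths in mm, angles in degrees, masses in kg,
inertias in kg m^2, spring coefficients in Nm (A) and dimensionless (B),
torsional damping in Nms/rad.  Unit conversion to SI happens when a
model is built, never here.
"""

from __future__ import annotations

# Chain order, base first.  C0 is the head; Ca is the massless auxiliary
# slider body used by the prismatic variant.
CHAIN_ORDER = ("T1", "C7", "C6", "C5", "C4", "C3", "C2", "C1", "C0")

JOINT_ORDER = (
    "C7/T1", "C6/C7", "C5/C6", "C4/C5", "C3/C4", "C2/C3", "C1/C2", "C0/C1",
)

# Body mass/inertia table and seated initial posture.
# name: (mass_kg, Ixx, Iyy, Izz, Sx_mm, Sz_mm, Gx_mm, Gz_mm, theta_deg)
# S is the body's frame origin in the parent body's local frame (T1 has no
# parent); G is the centre of mass in the body's own frame; theta is the
# initial absolute angle with the horizontal (flexion-positive).
# The published head CG row mixes units (27 mm / 0.043 m); it is stored
# here as 27 mm / 43 mm.
BODY_TABLE = {
    "C0": (4.69, 0.018, 0.024, 0.017, -2.0, 21.0, 27.0, 43.0, -13.0),
    "C1": (0.22, 0.001, 0.001, 0.002, 2.0, 16.0, -7.7, 0.0, -7.0),
    "C2": (0.25, 0.001, 0.001, 0.002, -2.0, 19.0, -7.7, 0.0, -7.0),
    "C3": (0.24, 0.001, 0.001, 0.002, -1.0, 18.0, -7.8, 0.0, -7.0),
    "C4": (0.23, 0.001, 0.001, 0.002, 2.0, 18.0, -7.9, 0.0, -12.0),
    "C5": (0.23, 0.001, 0.001, 0.002, 3.0, 17.0, -8.1, 0.0, -17.0),
    "C6": (0.24, 0.001, 0.001, 0.002, 6.0, 17.0, -8.3, 0.0, -23.0),
    "C7": (0.22, 0.001, 0.001, 0.002, 7.0, 17.0, -8.2, 0.0, -26.0),
    "T1": (0.86, 0.010, 0.010, 0.020, 0.0, 0.0, 0.0, 0.0, -26.0),
}

# Global position of the T1 frame origin (mm).
T1_GLOBAL_ORIGIN_MM = (4.0, 19.0)

# Initial (experimental, pre-identification) torsional spring coefficients.
# joint: (A1_Nm, B1, A2_Nm, B2).  Branch 1 is extension (theta < 0),
# branch 2 is flexion (theta >= 0).
STIFFNESS_INITIAL = {
    "C0/C1": (-0.0095, -0.3937, 0.0135, 0.3052),
    "C1/C2": (-0.0095, -0.3937, 0.0135, 0.3052),
    "C2/C3": (-0.0037, -1.0137, 0.1029, 0.4714),
    "C3/C4": (-0.0068, -1.1416, 0.0218, 0.7503),
    "C4/C5": (-0.0027, -1.6410, 0.1130, 0.3929),
    "C5/C6": (-0.0126, -0.9581, 0.0618, 0.5587),
    "C6/C7": (-0.0125, -1.2366, 0.1406, 0.5607),
    "C7/T1": (-0.3105, -0.6489, 0.6084, 0.3949),
}

# Constant torsional damping used by the initial model (no active muscle
# response is modelled, so the coefficient does not ramp in time).
DAMPING_INITIAL_NMS_PER_RAD = 1.8

# Final identified coefficients (modified model with the prismatic
# element).  joint: (A1_Nm, B1, A2_Nm, B2, C_Nms_per_rad)
STIFFNESS_FINAL = {
    "C0/C1": (-0.0071, -0.2215, 0.0159, 0.4131, 2.954),
    "C1/C2": (-0.0095, -0.3937, 0.0330, 0.7029, 4.395),
    "C2/C3": (-0.0037, -1.014, 0.2512, 0.8907, 1.582),
    "C3/C4": (-0.0068, -1.142, 0.0433, 1.173, 1.758),
    "C4/C5": (-0.0027, -1.641, 0.2335, 0.7685, 3.516),
    "C5/C6": (-0.01225, -0.9581, 0.1037, 1.027, 4.395),
    "C6/C7": (-0.0125, -1.237, 0.2057, 0.8521, 3.279),
    "C7/T1": (-0.3105, -0.6489, 1.322, 1.240, 3.516),
}

# Prismatic (C1-Ca) spring-damper: trial starting values and final
# identified values.
PRISMATIC_KV_INITIAL_N_PER_M = 10_000.0
PRISMATIC_CV_INITIAL_NS_PER_M = 100.0
PRISMATIC_KV_FINAL_N_PER_M = 1620.0
PRISMATIC_CV_FINAL_NS_PER_M = 100.0

# Position of the auxiliary slider body Ca, expressed like every other S
# entry: in the parent (C1) local frame, mm.  Ca shares C1's orientation
# and may only translate along the O_C1 -> O_Ca line.
CA_OFFSET_MM = (19.3, 142.0)

GRAVITY_M_PER_S2 = 9.81

# LAB sled-test pulse scalars (rigid seat, no head restraint).
LAB_PULSE_PEAK_G = 12.0
LAB_PULSE_DELTA_V_KMH = 10.0

# Nkm normalisation constants: shear force intercepts (anterior positive)
# and sagittal moment intercepts (flexion / extension).
NKM_FINT_N = 845.0
NKM_MINT_FLEXION_NM = 88.1
NKM_MINT_EXTENSION_NM = 47.5

PRESET_NAMES = ("V1-initial", "V5B-final")
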