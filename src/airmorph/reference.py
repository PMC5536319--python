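"""Published cohort summary statistics used to calibrate the simulator.

These tables summarize a 24-subject cohort of mild asthmatics imaged by
breath-hold HRCT at two inflation levels (mean lung volume, MLV, and total
lung capacity, TLC) after a methacholine challenge, with airway lumens
segmented down to generation 5.  They are the study conditions that the
synthetic-cohort generator emulates and that the consistency tests check
against; the package never treats them as measured input data.

All areas are mm^2, perimeters mm, lung volumes litres.  Each entry is a
``(mean, sd)`` pair over the cohort; ``None`` marks cells that could not
be measured (distal airways too small to segment at MLV).
"""

from __future__ import annotations

N_SUBJECTS = 24

# Per-lung air volumes at each inflation, (mean, sd) in litres.
LUNG_AIR_VOLUMES_L = {
    ("right", "MLV"): (1.294, 0.441),
    ("right", "TLC"): (2.286, 0.626),
    ("left", "MLV"): (1.136, 0.374),
    ("left", "TLC"): (2.072, 0.560),
}

# Cohort-average ratio of average inner diameter to hydraulic diameter.
DIN_DH_RATIO = {"MLV": (1.124, 0.068), "TLC": (1.108, 0.063)}

# Matched airways were reliably segmentable at MLV down to generation 5
# only in these segmental subtrees.
GEN5_MLV_SEGMENTS = ("RB1", "RB3", "RB6", "RB10", "LB3", "LB10")

# Fraction of matched airways whose hydraulic diameter decreased at TLC
# was below this bound in the study cohort.
MAX_FRACTION_DH_DECREASING = 0.05

# Mean lumen area (Ai) and inner perimeter (Pi) per airway and generation:
# {(label, generation): {"ai_mlv": (m, sd)|None, "ai_tlc": ..., "pi_mlv": ..., "pi_tlc": ...}}
def _g(ai_mlv, ai_tlc, pi_mlv, pi_tlc):
    return {"ai_mlv": ai_mlv, "ai_tlc": ai_tlc, "pi_mlv": pi_mlv, "pi_tlc": pi_tlc}


LUMEN_GEOMETRY = {
    # generations 0-2 (named proximal airways, lobar roots and trunks)
    ("T", 0): _g((162.20, 47.36), (181.43, 51.55), (47.80, 7.10), (49.44, 7.10)),
    ("R", 1): _g((120.50, 32.35), (141.17, 36.57), (40.47, 5.56), (43.40, 5.77)),
    ("L", 1): _g((72.00, 24.26), (88.06, 30.25), (30.80, 5.42), (33.78, 6.00)),
    ("RMI", 2): _g((66.86, 17.00), (77.83, 18.66), (30.25, 3.88), (32.53, 4.10)),
    ("RU", 2): _g((47.85, 17.94), (63.28, 19.67), (25.84, 5.50), (30.25, 5.05)),
    ("RM", 2): _g((21.76, 6.50), (27.30, 7.14), (16.75, 2.52), (18.77, 2.54)),
    ("LU", 2): _g((53.78, 17.89), (63.39, 18.26), (26.78, 4.41), (29.08, 4.46)),
    ("LL", 2): _g((47.87, 12.70), (62.37, 15.00), (25.53, 3.99), (29.16, 3.74)),
    ("LB4+5", 2): _g((21.64, 9.97), (28.01, 9.60), (16.58, 4.09), (18.89, 3.56)),
    ("LLR", 2): _g((28.59, 9.29), (40.50, 12.43), (19.10, 2.91), (22.56, 3.39)),
    # generation 3 (segmental bronchi)
    ("RB1", 3): _g((12.87, 7.00), (16.66, 6.78), (13.27, 4.41), (14.65, 2.96)),
    ("RB2", 3): _g((10.10, 3.74), (14.23, 5.00), (11.49, 2.00), (13.60, 2.31)),
    ("RB3", 3): _g((16.02, 7.16), (21.10, 8.98), (14.31, 2.95), (16.40, 3.29)),
    ("RB4", 3): _g((8.51, 2.67), (11.70, 6.64), (10.73, 1.72), (12.26, 3.02)),
    ("RB5", 3): _g((11.33, 3.48), (14.11, 3.77), (12.32, 1.80), (13.68, 1.85)),
    ("RB6", 3): _g((21.55, 22.47), (29.52, 29.47), (17.26, 9.09), (20.00, 10.09)),
    ("RB7", 3): _g((9.42, 3.83), (12.36, 5.57), (11.20, 2.43), (12.88, 3.36)),
    ("RB8", 3): _g((10.41, 2.72), (14.91, 4.41), (11.80, 1.45), (14.23, 2.24)),
    ("RB9", 3): _g((8.09, 1.86), (11.90, 4.21), (10.41, 1.24), (12.64, 2.64)),
    ("RB10", 3): _g((11.36, 3.47), (16.06, 5.90), (12.28, 1.77), (14.43, 2.29)),
    ("LB1", 3): _g((8.26, 2.13), (11.14, 3.47), (10.54, 1.34), (12.11, 1.72)),
    ("LB2", 3): _g((5.80, 2.07), (7.71, 2.95), (8.78, 1.45), (10.11, 1.77)),
    ("LB3", 3): _g((15.03, 9.31), (17.03, 6.78), (14.03, 3.97), (14.69, 3.09)),
    ("LB4", 3): _g((9.23, 2.67), (11.26, 4.14), (11.19, 1.47), (12.23, 2.32)),
    ("LB5", 3): _g((9.14, 3.35), (11.50, 4.46), (11.16, 1.85), (12.28, 2.30)),
    ("LB6", 3): _g((13.26, 3.65), (23.30, 8.55), (13.33, 1.77), (17.70, 3.42)),
    ("LB8", 3): _g((13.45, 3.45), (16.95, 4.44), (13.63, 1.66), (15.24, 2.34)),
    ("LB9", 3): _g((12.47, 4.68), (16.30, 5.75), (13.10, 2.23), (14.80, 3.32)),
    ("LB10", 3): _g((14.25, 6.93), (18.33, 5.52), (13.82, 3.29), (15.60, 2.55)),
    # generation 4 (first sub-segmental split)
    ("RB1", 4): _g((6.88, 2.11), (8.74, 3.02), (9.61, 1.38), (10.77, 1.75)),
    ("RB2", 4): _g((5.93, 1.39), (7.84, 2.79), (9.05, 1.10), (10.11, 1.65)),
    ("RB3", 4): _g((7.11, 2.57), (9.44, 3.53), (9.71, 1.56), (11.04, 1.86)),
    ("RB4", 4): _g((5.30, 1.49), (6.82, 2.29), (8.61, 1.17), (9.43, 1.66)),
    ("RB5", 4): _g((5.98, 2.11), (7.66, 2.33), (9.02, 1.61), (10.06, 1.69)),
    ("RB6", 4): _g((6.25, 2.09), (8.77, 3.39), (9.20, 1.52), (10.65, 2.05)),
    ("RB7", 4): _g((6.11, 1.40), (7.61, 2.71), (9.20, 1.01), (9.88, 1.79)),
    ("RB8", 4): _g((5.81, 3.53), (8.30, 4.95), (8.77, 2.27), (10.39, 2.69)),
    ("RB9", 4): _g((4.71, 1.90), (6.61, 2.25), (7.90, 1.55), (9.27, 1.51)),
    ("RB10", 4): _g((6.67, 3.16), (9.44, 4.54), (9.31, 2.25), (10.98, 2.85)),
    ("LB1", 4): _g((6.88, 1.80), (7.48, 2.61), (9.79, 1.28), (9.84, 1.69)),
    ("LB2", 4): _g(None, (6.86, 1.85), None, (9.78, 1.24)),
    ("LB3", 4): _g((2.50, 3.15), (9.42, 4.21), (14.03, 3.97), (10.90, 2.38)),
    ("LB4", 4): _g((6.66, 1.73), (7.56, 2.23), (9.43, 1.20), (9.85, 1.68)),
    ("LB5", 4): _g(None, (7.80, 1.47), None, (10.36, 0.92)),
    ("LB6", 4): _g((6.75, 1.29), (12.09, 8.11), (9.54, 0.81), (12.46, 4.02)),
    ("LB8", 4): _g((7.55, 1.54), (9.62, 3.32), (10.14, 0.94), (11.34, 1.94)),
    ("LB9", 4): _g((7.05, 2.73), (9.33, 4.16), (9.75, 1.91), (11.10, 2.36)),
    ("LB10", 4): _g((7.87, 3.95), (10.59, 5.62), (10.25, 2.56), (11.62, 3.12)),
    # generation 5 (second sub-segmental split; MLV often unsegmentable)
    ("RB1", 5): _g((6.04, 2.58), (6.54, 2.03), (8.99, 1.84), (9.13, 1.80)),
    ("RB2", 5): _g(None, (6.22, 2.04), None, (8.91, 1.87)),
    ("RB3", 5): _g((5.55, 1.16), (6.98, 2.63), (8.71, 0.84), (9.39, 2.00)),
    ("RB5", 5): _g(None, (5.95, 1.44), None, (9.16, 0.95)),
    ("RB6", 5): _g((4.40, 1.06), (6.29, 2.29), (7.75, 0.90), (9.22, 1.67)),
    ("RB8", 5): _g(None, (7.54, 1.73), None, (9.99, 1.71)),
    ("RB9", 5): _g(None, (4.99, 1.02), None, (8.37, 0.87)),
    ("RB10", 5): _g((5.99, 1.68), (8.12, 3.81), (8.94, 1.19), (10.22, 2.33)),
    ("LB3", 5): _g((6.43, 1.61), (7.69, 2.86), (9.44, 1.20), (10.12, 1.78)),
    ("LB4", 5): _g(None, (5.76, 1.37), None, (8.02, 2.36)),
    ("LB6", 5): _g(None, (6.83, 2.23), None, (9.40, 1.70)),
    ("LB8", 5): _g(None, (7.50, 1.70), None, (9.77, 1.36)),
    ("LB9", 5): _g(None, (9.30, 3.83), None, (11.08, 2.04)),
    ("LB10", 5): _g((6.43, 2.85), (7.98, 2.98), (9.45, 2.11), (10.03, 2.32)),
}

# Cohort hydraulic-diameter summary per lobe-region row and generation.
# Fields: dh mean/sd at each state (mm), per-airway percent change mean/sd,
# paired-test p (upper bound where reported as "<"), and the R^2 of the
# MLV-vs-TLC linear regression.
DH_SUMMARY = [
    # (group, generation, dh_mlv, sd, dh_tlc, sd, pct, sd, p, r2)
    ("T", 0, 13.48, 1.98, 14.61, 2.07, 7.7, 4.6, 0.0001, 0.876),
    ("R", 1, 11.74, 1.69, 12.86, 1.73, 8.7, 5.1, 0.0001, 0.853),
    ("L", 1, 9.09, 1.58, 10.12, 1.70, 10.1, 5.2, 0.0001, 0.883),
    ("RMI", 2, 8.68, 1.22, 9.40, 1.22, 7.7, 4.0, 0.0001, 0.895),
    ("RU", 2, 7.17, 1.29, 8.23, 1.25, 12.6, 10.6, 0.0001, 0.469),
    ("RB1-3", 3, 3.82, 0.80, 4.47, 0.90, 14.4, 7.6, 0.0001, 0.848),
    ("RB1-3", 4, 2.75, 0.43, 3.25, 0.58, 14.4, 10.4, 0.0001, 0.582),
    ("RB1-3", 5, 2.55, 0.41, 2.91, 0.37, 10.8, 13.8, 0.0267, 0.451),
    ("RM", 2, 5.11, 0.79, 5.75, 0.75, 11.1, 7.3, 0.0001, 0.718),
    ("RB4-5", 3, 3.37, 0.44, 3.85, 0.69, 11.7, 7.7, 0.0001, 0.785),
    ("RB4-5", 4, 2.53, 0.40, 2.89, 0.47, 12.0, 9.8, 0.0001, 0.608),
    ("RL", 2, 8.12, 1.57, 8.37, 1.57, 2.8, 10.7, 0.2394, 0.715),
    ("RB6-10", 3, 3.57, 0.72, 4.21, 0.91, 14.4, 9.4, 0.0001, 0.730),
    ("RB6-10", 4, 2.57, 0.50, 3.09, 0.65, 16.1, 9.0, 0.0001, 0.712),
    ("RB6-10", 5, 2.44, 0.35, 2.81, 0.43, 13.1, 12.3, 0.0520, 0.281),
    ("LU", 2, 7.84, 1.33, 8.55, 1.21, 8.3, 6.7, 0.0001, 0.801),
    ("LB1-5", 3, 3.24, 0.60, 3.73, 0.64, 12.9, 8.9, 0.0055, 0.719),
    ("LB1-5", 4, 2.84, 0.47, 2.83, 0.61, 12.8, 8.7, 0.0098, 0.723),
    ("LB1-5", 5, 2.69, 0.36, 3.16, 0.60, 13.3, 13.2, 0.0024, 0.370),
    ("LL", 2, 7.34, 0.86, 8.45, 1.02, 13.0, 5.7, 0.0001, 0.706),
    ("LB6-10", 3, 3.92, 0.65, 4.73, 0.82, 16.0, 10.2, 0.0001, 0.592),
    ("LB6-10", 4, 2.88, 1.05, 3.65, 1.55, 19.6, 9.0, 0.0001, 0.647),
    ("LB6-10", 5, 2.61, 0.60, 3.25, 0.68, 19.5, 7.0, 0.0012, 0.881),
]

# Airways whose single-label rows in the geometry table correspond one-to-one
# to rows of the hydraulic-diameter summary (the pooled "RBx-y" rows do not).
DH_SUMMARY_LABEL_ROWS = {
    "T": ("T", 0),
    "R": ("R", 1),
    "L": ("L", 1),
    "RMI": ("RMI", 2),
    "RU": ("RU", 2),
    "RM": ("RM", 2),
    "LU": ("LU", 2),
    "LL": ("LL", 2),
}

# Volume-normalized distensibility per segmental subtree and generation:
# {(label, generation): (mean, sd, r2)} where r2 is the correlation between
# relative lumen-area change and relative lung-volume change.
DISTENSIBILITY = {
    ("RB1", 3): (0.41, 0.34, 0.0016),
    ("RB1", 4): (0.47, 0.27, 0.3198),
    ("RB1", 5): (0.32, 0.19, 0.0608),
    ("RB2", 3): (0.51, 0.29, 0.2117),
    ("RB2", 4): (0.54, 0.42, 0.4444),
    ("RB3", 3): (0.37, 0.17, 0.3620),
    ("RB3", 4): (0.43, 0.21, 0.1681),
    ("RB3", 5): (0.39, 0.29, 0.0500),
    ("RB4", 3): (0.35, 0.23, 0.1098),
    ("RB4", 4): (0.44, 0.27, 0.2999),
    ("RB5", 3): (0.28, 0.15, 0.4362),
    ("RB5", 4): (0.33, 0.28, 0.2910),
    ("RB6", 3): (0.37, 0.62, 0.2261),
    ("RB6", 4): (0.60, 0.45, 0.2129),
    ("RB7", 3): (0.29, 0.22, 0.2289),
    ("RB7", 4): (0.26, 0.14, 0.3904),
    ("RB8", 3): (0.51, 0.32, 0.0623),
    ("RB8", 4): (0.47, 0.21, 0.2720),
    ("RB9", 3): (0.49, 0.23, 0.3592),
    ("RB9", 4): (0.71, 0.41, 0.1232),
    ("RB10", 3): (0.57, 0.22, 0.5890),
    ("RB10", 4): (0.56, 0.33, 0.1485),
    ("RB10", 5): (0.39, 0.31, 0.7208),
    ("LB1", 3): (0.49, 0.24, 0.1498),
    ("LB1", 4): (0.12, 0.17, 0.9170),
    ("LB2", 3): (0.49, 0.30, 0.1691),
    ("LB3", 3): (0.32, 0.23, 0.4119),
    ("LB3", 4): (0.44, 0.32, 0.0628),
    ("LB3", 5): (0.33, 0.33, 0.7561),
    ("LB4", 3): (0.36, 0.31, 0.5752),
    ("LB4", 4): (0.31, 0.22, 0.3183),
    ("LB5", 3): (0.35, 0.20, 0.6899),
    ("LB6", 3): (0.83, 0.31, 0.3260),
    ("LB6", 4): (0.91, 0.51, 0.5461),
    ("LB8", 3): (0.27, 0.22, 0.0710),
    ("LB8", 4): (0.37, 0.22, 0.3233),
    ("LB9", 3): (0.51, 0.33, 0.6615),
    ("LB9", 4): (0.63, 0.15, 0.5838),
    ("LB10", 3): (0.48, 0.31, 0.4362),
    ("LB10", 4): (0.52, 0.24, 0.4303),
    ("LB10", 5): (0.64, 0.22, 0.6476),
}

# Cohort mean distensibility over all segments and generations.
MEAN_DISTENSIBILITY = (0.45, 0.28)

# Correlation between per-subtree mean distensibility at generation 3 and 4,
# for the full set of subtrees and with the LB1 subtree excluded.
GEN3_VS_GEN4_R2 = {"full": 0.4793, "LB1_excluded": 0.7401}


def mean_rel_volume_change(side: str) -> float:
    """Cohort-mean relative volume change (V_TLC - V_MLV) / V_MLV of one lung,
    computed from the mean per-lung volumes."""
    v_mlv = LUNG_AIR_VOLUMES_L[(side, "MLV")][0]
    v_tlc = LUNG_AIR_VOLUMES_L[(side, "TLC")][0]
    return (v_tlc - v_mlv) / v_mlv
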