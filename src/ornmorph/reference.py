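"""Published population summary statistics for ab1 sensilla and their
CO2-sensing (ab1C) and odor-sensing (ab1D) neurons.

These printed mean ± SD values, category counts and text-level ranges are the
inputs for derived-ratio analyses and the calibration targets of the
synthetic-population generator.  Units: µm (length), µm² (surface area),
µm³ (volume), µm² (V/L, the mean cross-sectional area), µm⁻¹ (S/V).

Each per-category entry maps segment -> metric -> (mean, sd).  ``proximal``
is the cylindrical/unbranched trunk of the outer dendrite, ``distal`` the
flattened (ab1C) or branched (ab1D) part, ``total`` their combination.
"""

from __future__ import annotations

# -- outer dendritic segment morphometrics (mean, sd) -----------------------

AB1C_CATEGORY_COUNTS = {
    "loosely_curled": 13,
    "fully_curled": 5,
    "split": 4,
    "mixed": 3,
}

AB1D_CATEGORY_COUNTS = {"unbranched": 8, "branched": 13}

AB1C_SEGMENTS = {
    "loosely_curled": {
        "proximal": {"length": (10.67, 0.86), "surface_area": (19.82, 2.10), "volume": (2.60, 0.34)},
        "distal": {"length": (5.73, 0.84), "surface_area": (23.90, 3.69), "volume": (1.07, 0.16)},
        "total": {"length": (16.40, 1.41), "surface_area": (43.72, 3.91), "volume": (3.68, 0.36)},
    },
    "fully_curled": {
        "proximal": {"length": (11.62, 0.88), "surface_area": (20.86, 2.03), "volume": (2.73, 0.26)},
        "distal": {"length": (5.64, 0.62), "surface_area": (24.66, 5.03), "volume": (0.91, 0.35)},
        "total": {"length": (17.27, 0.78), "surface_area": (45.52, 4.37), "volume": (3.64, 0.43)},
    },
    "split": {
        "proximal": {"length": (10.76, 0.59), "surface_area": (20.33, 2.61), "volume": (2.80, 0.49)},
        "distal": {"length": (4.78, 0.71), "surface_area": (21.00, 6.12), "volume": (0.91, 0.23)},
        "total": {"length": (15.54, 0.48), "surface_area": (41.33, 7.32), "volume": (3.71, 0.66)},
    },
    "mixed": {
        "proximal": {"length": (9.38, 0.68), "surface_area": (18.07, 1.43), "volume": (2.40, 0.16)},
        "distal": {"length": (7.26, 0.33), "surface_area": (28.92, 7.44), "volume": (1.21, 0.45)},
        "total": {"length": (16.64, 0.93), "surface_area": (47.00, 6.73), "volume": (3.61, 0.30)},
    },
}

AB1C_TOTAL_ROW = {
    "n": 25,
    "proximal": {"length": (10.72, 0.97), "surface_area": (19.90, 2.09), "volume": (2.64, 0.33),
                 "volume_per_length": (0.25, 0.03), "sa_to_v": (7.58, 0.50)},
    "distal": {"length": (5.74, 0.95), "surface_area": (24.19, 4.89), "volume": (1.03, 0.25),
               "volume_per_length": (0.18, 0.05), "sa_to_v": (23.94, 3.93)},
    "total": {"length": (16.47, 1.19), "surface_area": (44.09, 4.81), "volume": (3.67, 0.39),
              "volume_per_length": (0.22, 0.03), "sa_to_v": (12.07, 1.11)},
}

AB1D_SEGMENTS = {
    "unbranched": {
        "total": {"length": (17.47, 1.85), "surface_area": (13.29, 1.18), "volume": (0.69, 0.08),
                  "volume_per_length": (0.040, 0.006), "sa_to_v": (19.50, 2.13)},
    },
    "branched": {
        "proximal": {"length": (8.94, 1.11), "surface_area": (8.97, 1.72), "volume": (0.60, 0.10),
                     "volume_per_length": (0.068, 0.014), "sa_to_v": (15.03, 1.63)},
        "distal": {"length": (29.09, 10.25), "surface_area": (10.77, 3.30), "volume": (0.30, 0.10),
                   "volume_per_length": (0.010, 0.003), "sa_to_v": (37.51, 4.18)},
        "total": {"length": (38.83, 10.05), "surface_area": (19.74, 4.12), "volume": (0.90, 0.20),
                  "volume_per_length": (0.025, 0.006), "sa_to_v": (22.25, 2.65)},
    },
}

AB1D_TOTAL_ROW = {
    "n": 21,
    "total": {"length": (30.20, 12.78), "surface_area": (17.28, 4.57), "volume": (0.82, 0.18),
              "volume_per_length": (0.030, 0.010), "sa_to_v": (21.20, 2.81)},
}

# -- sensillum cuticle morphometrics -----------------------------------------

CUTICLE = {
    "length": (9.50, 0.98),  # µm, n=31
    "surface_area": (93.75, 5.83),  # µm², n=31
    "volume": (46.09, 3.91),  # µm³, n=31
    "n": 31,
}

DENDRITE_COUNT = {"mean": 136, "sd": 29, "n": 32, "range": (65, 295)}

# -- landmark positions (cuticle proportions) --------------------------------

AB1C_FLATTENING = {"range": (0.13, 0.53), "mean": 0.40}
AB1C_TERMINUS = {"range": (0.62, 0.98), "mean": 0.89}
AB1D_BRANCH_POINT = {"range": (0.08, 0.44), "mean": 0.21, "sd": 0.10}
AB1D_TERMINUS = {"range": (0.63, 0.97), "mean": 0.91, "sd": 0.08}

# -- sizes and ranges --------------------------------------------------------

# relative neuronal size ratio A : B : C : D (combined soma + inner dendrite
# + outer dendrite surface areas track extracellular spike amplitudes)
ORN_SIZE_RATIO = {"ab1A": 5.2, "ab1B": 4.5, "ab1C": 2.3, "ab1D": 1.0}

AB1C_SA_RANGE = (30.67, 54.75)  # µm², spans 1.78-fold
AB1D_SA_RANGE = (11.77, 26.08)  # µm², spans 2.21-fold

AB1D_BRANCH_COUNT_RANGE = (2, 7)
# average dimensions of a single distal ab1D branch
AB1D_BRANCH_DIMS = {"length": 6.00, "surface_area": 2.22, "volume": 0.06}

SOMA_VOLUME = {"ab1C": 42.68, "ab1D": 23.73}  # µm³
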