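"""Frozen published values for the worked phthalate example.

Column keys are receptor ids; compound order follows the acute-toxicity
panel fixture.  Differences are printed to six decimals, coefficients
and degrees to four, change rates to one or two — tolerances in the
tests mirror those printing precisions.
"""

RECEPTORS = ["green_algae", "daphnid", "mysid", "fish"]

# Absolute differences |1.0 - value| per compound and receptor (6 dp).
EXPECTED_DIFFERENCES = {
    "DEHP": {"fish": 0.990000, "green_algae": 0.998430, "daphnid": 0.990000, "mysid": 0.999581},
    "DIDP": {"fish": 0.999213, "green_algae": 0.999924, "daphnid": 0.999331, "mysid": 0.999989},
    "DNOP": {"fish": 0.992000, "green_algae": 0.998760, "daphnid": 0.992000, "mysid": 0.999683},
    "DPP": {"fish": 0.673000, "green_algae": 0.889000, "daphnid": 0.537000, "mysid": 0.933000},
    "DCHP": {"fish": 0.845000, "green_algae": 0.955000, "daphnid": 0.794000, "mysid": 0.977000},
    "DUP": {"fish": 0.999817, "green_algae": 0.999987, "daphnid": 0.999862, "mysid": 0.999999},
    "BCHP": {"fish": 0.583000, "green_algae": 0.851000, "daphnid": 0.398000, "mysid": 0.905000},
    "BDP": {"fish": 0.972000, "green_algae": 0.994000, "daphnid": 0.968000, "mysid": 0.998100},
    "BMPP": {"fish": 0.884000, "green_algae": 0.968000, "daphnid": 0.850000, "mysid": 0.985000},
    "BOP": {"fish": 0.905000, "green_algae": 0.975000, "daphnid": 0.879000, "mysid": 0.989000},
    "DINP": {"fish": 0.998000, "green_algae": 0.999728, "daphnid": 0.998000, "mysid": 0.999947},
    "DIPP": {"fish": 0.602000, "green_algae": 0.859000, "daphnid": 0.427000, "mysid": 0.912000},
    "DNDP": {"fish": 0.999354, "green_algae": 0.999940, "daphnid": 0.999460, "mysid": 0.999991},
    "HEHP": {"fish": 0.970000, "green_algae": 0.994000, "daphnid": 0.965000, "mysid": 0.998000},
}

# Per-sequence difference extremes over compounds (6 dp).
EXPECTED_COLUMN_MIN = {"fish": 0.583000, "green_algae": 0.851000,
                       "daphnid": 0.398000, "mysid": 0.905000}
EXPECTED_COLUMN_MAX = {"fish": 0.999817, "green_algae": 0.999987,
                       "daphnid": 0.999862, "mysid": 0.999999}

# Grey coefficients (per-sequence extremes, rho = 0.5) and degrees (4 dp).
EXPECTED_COEFFICIENTS = {
    "DEHP": {"fish": 0.7268, "green_algae": 0.9016, "daphnid": 0.6027, "mysid": 0.9369},
    "DIDP": {"fish": 0.7224, "green_algae": 0.9007, "daphnid": 0.5989, "mysid": 0.9367},
    "DNOP": {"fish": 0.7259, "green_algae": 0.9014, "daphnid": 0.6019, "mysid": 0.9369},
    "DPP": {"fish": 0.9233, "green_algae": 0.9726, "daphnid": 0.8660, "mysid": 0.9805},
    "DCHP": {"fish": 0.8052, "green_algae": 0.9285, "daphnid": 0.6940, "mysid": 0.9513},
    "DUP": {"fish": 0.7221, "green_algae": 0.9007, "daphnid": 0.5987, "mysid": 0.9367},
    "BCHP": {"fish": 1.0000, "green_algae": 1.0000, "daphnid": 1.0000, "mysid": 1.0000},
    "BDP": {"fish": 0.7357, "green_algae": 0.9043, "daphnid": 0.6117, "mysid": 0.9379},
    "BMPP": {"fish": 0.7825, "green_algae": 0.9203, "daphnid": 0.6652, "mysid": 0.9461},
    "BOP": {"fish": 0.7708, "green_algae": 0.9159, "daphnid": 0.6512, "mysid": 0.9436},
    "DINP": {"fish": 0.7229, "green_algae": 0.9008, "daphnid": 0.5994, "mysid": 0.9367},
    "DIPP": {"fish": 0.9828, "green_algae": 0.9941, "daphnid": 0.9687, "mysid": 0.9950},
    "DNDP": {"fish": 0.7223, "green_algae": 0.9007, "daphnid": 0.5989, "mysid": 0.9367},
    "HEHP": {"fish": 0.7367, "green_algae": 0.9043, "daphnid": 0.6130, "mysid": 0.9379},
}

EXPECTED_DEGREES = {
    "DEHP": 0.7920, "DIDP": 0.7897, "DNOP": 0.7915, "DPP": 0.9356,
    "DCHP": 0.8447, "DUP": 0.7895, "BCHP": 1.0000, "BDP": 0.7974,
    "BMPP": 0.8285, "BOP": 0.8204, "DINP": 0.7900, "DIPP": 0.9852,
    "DNDP": 0.7896, "HEHP": 0.7980,
}

# The per-sequence vs double-extreme disagreement cell: DEHP's fish
# coefficient is 0.7268 with fish-column extremes but 0.6027 with the
# global extremes (which coincide with the daphnid column's).
DIVERGENCE_CELL = ("DEHP", "fish")
DIVERGENCE_PER_SEQUENCE = 0.7268
DIVERGENCE_GLOBAL = 0.6027

# Stage-1 screen: published change rates (%) of the derivative
# comprehensive-characterization estimates, 2 dp, fixture order.
ACTIVITY_RATES = {
    "DINP-CH3": 14.54, "DINP-CH2CH3": -2.43, "DINP-CH2CH2CH3": 11.95,
    "DINP-CH=CH2": 15.00, "DINP-C6H5": 13.29, "DINP-OCH3": 58.86,
    "DINP-Cl": -5.72, "DINP-F": 39.70, "DINP-Br": 37.37,
    "DINP-SH": 208.12, "DINP-NO2": 136.13,
    "DEHP-CH3": 0.01, "DEHP-CH2CH3": 35.72, "DEHP-CH2CH2CH3": 0.20,
    "DEHP-CH=CH2": 13.02, "DEHP-C6H5": 16.13, "DEHP-OCH3": 48.07,
    "DEHP-Cl": 6.25, "DEHP-F": 21.89, "DEHP-Br": 14.96,
    "DEHP-SH": 3.64, "DEHP-NO2": 20.00,
}

STAGE1_EXPECTED_PASSED = 16
STAGE1_PASSED_AT_50PCT = {"DINP-OCH3", "DINP-SH", "DINP-NO2"}

# Stage-2 screen: published per-receptor pToxicity change rates (%), 2 dp.
PTOX_RATES = {
    "DINP-CH3": {"green_algae": -65.73, "daphnid": -78.57, "mysid": -65.07, "fish": -73.70},
    "DINP-CH2CH2CH3": {"green_algae": -47.10, "daphnid": -56.98, "mysid": -46.23, "fish": -53.90},
    "DINP-CH=CH2": {"green_algae": -59.16, "daphnid": -70.91, "mysid": -58.65, "fish": -66.67},
    "DINP-C6H5": {"green_algae": -43.91, "daphnid": -53.03, "mysid": -43.96, "fish": -50.10},
    "DINP-OCH3": {"green_algae": -90.88, "daphnid": -108.71, "mysid": -89.66, "fish": -101.68},
    "DINP-F": {"green_algae": -76.56, "daphnid": -91.62, "mysid": -75.67, "fish": -85.81},
    "DINP-Br": {"green_algae": -70.80, "daphnid": -84.97, "mysid": -69.59, "fish": -79.86},
    "DINP-SH": {"green_algae": -77.05, "daphnid": -92.23, "mysid": -76.11, "fish": -86.42},
    "DINP-NO2": {"green_algae": -93.45, "daphnid": -111.83, "mysid": -92.12, "fish": -104.63},
    "DEHP-CH2CH3": {"green_algae": 11.73, "daphnid": 15.05, "mysid": 11.52, "fish": 15.05},
    "DEHP-CH=CH2": {"green_algae": 8.41, "daphnid": 11.09, "mysid": 8.28, "fish": 11.09},
    "DEHP-C6H5": {"green_algae": 28.09, "daphnid": 34.95, "mysid": 27.80, "fish": 34.95},
    "DEHP-OCH3": {"green_algae": -31.50, "daphnid": -40.65, "mysid": -31.88, "fish": -36.62},
    "DEHP-F": {"green_algae": -14.48, "daphnid": -18.09, "mysid": -13.53, "fish": -15.05},
    "DEHP-Br": {"green_algae": -3.75, "daphnid": -8.80, "mysid": -5.57, "fish": -7.31},
    "DEHP-NO2": {"green_algae": -34.96, "daphnid": -44.88, "mysid": -34.22, "fish": -40.65},
}

STAGE2_EXPECTED_PASSED = {
    "DINP-CH3", "DINP-CH2CH2CH3", "DINP-CH=CH2", "DINP-C6H5", "DINP-OCH3",
    "DINP-F", "DINP-Br", "DINP-SH", "DINP-NO2",
    "DEHP-OCH3", "DEHP-F", "DEHP-Br", "DEHP-NO2",
}

# Functional / POPs / docking / metabolite / barrier published change
# rates: (printed value, decimals printed).
FUNCTIONAL_RATES = {
    "DINP-C6H5": {"energy": (-6.34, 2), "gap": (-5.99, 2)},
    "DEHP-F": {"energy": (4.84, 2), "gap": (-1.26, 2)},
}
POPS_RATES = {
    "DINP-C6H5": {"log_koa": (-8.88, 2), "log_kow": (-22.84, 2), "half_life": (29.1, 1)},
    "DEHP-F": {"log_koa": (-12.56, 2), "log_kow": (-6.56, 2), "half_life": (9.4, 1)},
}
DOCKING_RATES = {
    "DINP-C6H5": {"1BA9": (-14.1, 1), "3DWV": (-10.5, 1), "3ZXX": (-7.9, 1), "3KDT": (-19.8, 1)},
    "DEHP-F": {"1BA9": (-19.2, 1), "3DWV": (-5.9, 1), "3ZXX": (-8.1, 1), "3KDT": (-3.9, 1)},
}
METABOLITE_RATES = {
    "MINP-C6H5": {"green_algae": (2683.4, 1), "daphnid": (1880.3, 1),
                  "mysid": (5070.1, 1), "fish": (1473.4, 1)},
    "MEHP-F": {"green_algae": (146.1, 1), "daphnid": (125.5, 1),
               "mysid": (188.41, 2), "fish": (112.6, 1)},
}
BARRIER_RATES = {"DINP-C6H5": (-88.5, 1), "DEHP-F": (-92.4, 1)}

# Published signed error ratios of the pharmacophore fit table (2 dp).
FIT_ERRORS = {
    "DINP": -1.10, "DEHP": -1.06, "BDP": -1.01, "BOP": -1.03, "HEHP": 1.01,
    "DNOP": 1.03, "DPP": -1.11, "BMPP": 1.05, "DCHP": 1.07, "BCHP": 1.09,
    "DIDP": -1.20, "DUP": 1.06, "DNDP": 1.13, "DIPP": 1.03,
}

# Negative-log values of the parent compounds as printed in the stage-2
# table (4 dp) — must equal -log10 of the acute-toxicity panel cells.
PARENT_PTOX = {
    "DINP": {"green_algae": 3.5654, "daphnid": 2.6990, "mysid": 4.2790, "fish": 2.6990},
    "DEHP": {"green_algae": 2.8041, "daphnid": 2.0000, "mysid": 3.3778, "fish": 2.0000},
}


def tolerance(decimals: int) -> float:
    """Half a unit in the last printed digit (0.05 for 1 dp, 0.005 for 2),
    widened to 0.01 for 2-dp change-rate cells per the comparison rule."""
    return 0.05 if decimals == 1 else 0.01
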