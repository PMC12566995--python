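"""Published quantities from the *Licaria armeniaca* ultrasound-assisted
extraction case study that this package's worked examples reproduce.

The study ran a 3-factor rotatable central composite design (8 factorial +
6 axial + 3 center runs) on ethanol percentage, extraction time and
solid-to-liquid ratio, with DPPH inhibition and total phenolic content as
responses.  The run-level responses were never published, but the fitted
reduced models, the ANOVA components, the factor coding table, the
gallic-acid calibration points and the cytotoxicity IC50 table were — those
printed values are collected here as inputs for validation and examples.

Coefficients are the printed 2-decimal values; coded levels derive from the
(center, step) pairs whose rounded images match the printed level table.
"""

from __future__ import annotations

from .design import Factor

# Factor coding: actual = center + coded * step, step = level(+1) - level(0)
FACTOR_ETOH = Factor("X1", "% EtOH", center=50.0, step=29.76)
FACTOR_TIME = Factor("X2", "min", center=35.0, step=17.86)
FACTOR_SLR_LEAVES = Factor("X3", "% m/v", center=4.4, step=2.14, display_decimals=2)
FACTOR_SLR_BRANCHES = Factor("X3", "% m/v", center=11.0, step=5.35, display_decimals=2)

FACTORS_LEAVES = [FACTOR_ETOH, FACTOR_TIME, FACTOR_SLR_LEAVES]
FACTORS_BRANCHES = [FACTOR_ETOH, FACTOR_TIME, FACTOR_SLR_BRANCHES]

# Printed coded-level table: factor name -> {coded level: actual level}
PRINTED_LEVELS = {
    "etoh": {-1.68: 0.0, -1: 20.24, 0: 50.0, 1: 79.76, 1.68: 100.0},
    "time": {-1.68: 5.0, -1: 17.14, 0: 35.0, 1: 52.86, 1.68: 65.0},
    "slr_leaves": {-1.68: 0.8, -1: 2.24, 0: 4.4, 1: 6.54, 1.68: 8.0},
    "slr_branches": {-1.68: 2.0, -1: 5.56, 0: 11.0, 1: 16.35, 1.68: 20.0},
}

# Reduced model for leaves DPPH inhibition (%): 3 linear, 3 quadratic,
# 2 interaction terms retained at p <= 0.1
EQ_LEAVES_DPPH = {
    "1": 65.26,
    "X1": 5.92,
    "X2": 2.63,
    "X3": 1.99,
    "X1^2": -11.89,
    "X2^2": -1.68,
    "X3^2": -1.96,
    "X1*X2": 4.40,
    "X1*X3": 3.32,
}

# Reduced model for thin-branch TPC (mg GAE/g): X2*X3 retained without X3
EQ_BRANCHES_TPC = {
    "1": 328.61,
    "X1": 38.13,
    "X2": 13.64,
    "X2*X3": -20.69,
}

# Desirability-tool optima as published (coded), with predicted responses
OPTIMUM_LEAVES = {
    "coded": (0.5, -0.5, 1.5),
    "predicted_dpph": 63.48,
    "predicted_tpc": 233.39,
    "global_d": 0.9199,
}
OPTIMUM_BRANCHES = {
    "coded": (0.0, 1.68, 1.68),
    "predicted_tpc": 291.30,
    "global_d": 0.957,
}

# Validation: mean absolute relative error (%) between predicted and
# observed replicates at the optimum
VALIDATION_MAE = {"leaves_dpph": 1.78, "branches_tpc": 3.33}

# Published ANOVA components: (SS, df) per source, plus printed F and R2
ANOVA_COMPONENTS = {
    "leaves_dpph": {
        "regression": (2515.1, 8),
        "residual": (177.1, 8),
        "lof": (170.710, 6),
        "pure_error": (6.383, 2),
        "total": (2692.234, 16),
        "f_regression": 14.20,
        "f_tab_regression": 2.59,
        "f_lof": 8.92,
        "f_tab_lof": 9.33,
        "r2": 0.9342,
    },
    "branches_tpc": {
        "regression": (26343.4, 3),
        "residual": (9335.7, 13),
        "lof": (9034.92, 11),
        "pure_error": (300.81, 2),
        "total": (35679.12, 16),
        "f_regression": 12.23,
        "f_tab_regression": 2.56,
        "f_lof": 5.46,
        "f_tab_lof": 9.4,
        "r2": 0.7383,
    },
    "branches_dpph": {
        "regression": (582.0, 8),
        "residual": (397.1, 8),
        "lof": (394.0452, 6),
        "pure_error": (3.0824, 2),
        "total": (979.1334, 16),
        "f_regression": 1.47,
        "f_tab_regression": 2.59,
        "f_lof": 42.61,
        "f_tab_lof": 9.33,
        "r2": 0.5944,
    },
}

# Gallic-acid calibration for the Folin-Ciocalteu TPC assay (triplicate means)
CALIBRATION_CONC_MG_L = (2.0, 4.0, 8.0, 16.0, 24.0, 32.0, 40.0)
CALIBRATION_ABSORBANCE = (0.04, 0.11, 0.24, 0.44, 0.64, 0.87, 1.05)
CALIBRATION_R2 = 0.998

# Cytotoxicity IC50 (µg/mL) per extract and cell line; RAW 264.7 is the
# normal line used as the selectivity-index numerator
IC50 = {
    "leaves": {"AGP-01": 27.63, "AHOL": 11.52, "A549": 45.97, "RAW264.7": 28.81},
    "thin_branches": {"AGP-01": 15.71, "AHOL": 18.89, "A549": 31.5, "RAW264.7": 14.72},
    "thick_branches": {"AGP-01": 13.59, "AHOL": 26.52, "A549": 16.95, "RAW264.7": 50.86},
}
SI_PRINTED = {
    "leaves": {"AGP-01": 1.04, "AHOL": 2.5, "A549": 0.63},
    "thin_branches": {"AGP-01": 0.94, "AHOL": 0.78, "A549": 0.47},
    "thick_branches": {"AGP-01": 3.74, "AHOL": 1.92, "A549": 3.0},
}

# Pure-error mean square of the leaves DPPH table anchors the synthetic
# noise level: sd = sqrt(3.191) ~= 1.79
NOISE_SD_DPPH = 1.79
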