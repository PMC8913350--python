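"""Default study presets for a mouse Chkb-knockout cardiac phenotyping study.

The package ships one set of defaults describing the study design it was
written around: three genotypes (wildtype ``WT``, heterozygous ``HET``,
homozygous knockout ``KO``), triplicate biological replicates for lipidomics,
thirteen lipid classes with reported class-level median fold-changes, and
per-genotype echocardiography group means.  All of them are plain data — the
generators and validation checks take them as inputs, and every one is
overridable through the simulation configs.
"""

from __future__ import annotations

GENOTYPES = ("WT", "HET", "KO")

COMPARISONS = ("HET_vs_WT", "KO_vs_WT")

#: The thirteen lipid classes quantified in the emulated study, in report order.
LIPID_CLASSES = (
    "AcCa", "Cer", "CL", "DG", "LPC", "LPE", "PC",
    "PE", "PG", "PI", "PS", "SM", "TG",
)

#: Reported class-level median fold-changes (mutant over wildtype) used as the
#: generator's true-effect presets: class -> {comparison -> fold-change}.
DEFAULT_CLASS_FC: dict[str, dict[str, float]] = {
    "AcCa": {"HET_vs_WT": 1.68, "KO_vs_WT": 3.07},
    "Cer":  {"HET_vs_WT": 0.60, "KO_vs_WT": 0.65},
    "CL":   {"HET_vs_WT": 1.67, "KO_vs_WT": 1.40},
    "DG":   {"HET_vs_WT": 1.37, "KO_vs_WT": 1.05},
    "LPC":  {"HET_vs_WT": 0.62, "KO_vs_WT": 0.52},
    "LPE":  {"HET_vs_WT": 0.54, "KO_vs_WT": 0.79},
    "PC":   {"HET_vs_WT": 1.18, "KO_vs_WT": 1.35},
    "PE":   {"HET_vs_WT": 1.24, "KO_vs_WT": 1.04},
    "PG":   {"HET_vs_WT": 0.64, "KO_vs_WT": 1.21},
    "PI":   {"HET_vs_WT": 0.87, "KO_vs_WT": 1.24},
    "PS":   {"HET_vs_WT": 1.74, "KO_vs_WT": 0.88},
    "SM":   {"HET_vs_WT": 0.82, "KO_vs_WT": 1.06},
    "TG":   {"HET_vs_WT": 1.19, "KO_vs_WT": 0.55},
}

#: Class-level p-values reported by the emulated study's own analysis
#: (class -> {comparison -> p}).  Used to validate the family-wise control
#: stage: feeding these 26 p-values through Bonferroni dual reporting must
#: reproduce the study's published significance markers.
REPORTED_CLASS_PVALUES: dict[str, dict[str, float]] = {
    "AcCa": {"HET_vs_WT": 0.0053, "KO_vs_WT": 0.0002},
    "Cer":  {"HET_vs_WT": 0.0000, "KO_vs_WT": 0.0000},
    "CL":   {"HET_vs_WT": 0.0000, "KO_vs_WT": 0.0074},
    "DG":   {"HET_vs_WT": 0.0000, "KO_vs_WT": 0.5291},
    "LPC":  {"HET_vs_WT": 0.0001, "KO_vs_WT": 0.0007},
    "LPE":  {"HET_vs_WT": 0.0039, "KO_vs_WT": 0.2500},
    "PC":   {"HET_vs_WT": 0.0000, "KO_vs_WT": 0.0000},
    "PE":   {"HET_vs_WT": 0.0071, "KO_vs_WT": 0.7155},
    "PG":   {"HET_vs_WT": 0.8125, "KO_vs_WT": 1.0000},
    "PI":   {"HET_vs_WT": 0.7819, "KO_vs_WT": 0.0174},
    "PS":   {"HET_vs_WT": 0.0625, "KO_vs_WT": 0.6250},
    "SM":   {"HET_vs_WT": 0.0027, "KO_vs_WT": 0.3777},
    "TG":   {"HET_vs_WT": 0.0418, "KO_vs_WT": 0.0155},
}

#: Published significance markers matching REPORTED_CLASS_PVALUES
#: ("" none, "*" pre-correction only, "***" survives Bonferroni).
REPORTED_CLASS_MARKERS: dict[str, dict[str, str]] = {
    "AcCa": {"HET_vs_WT": "*",   "KO_vs_WT": "***"},
    "Cer":  {"HET_vs_WT": "***", "KO_vs_WT": "***"},
    "CL":   {"HET_vs_WT": "***", "KO_vs_WT": "*"},
    "DG":   {"HET_vs_WT": "***", "KO_vs_WT": ""},
    "LPC":  {"HET_vs_WT": "***", "KO_vs_WT": "***"},
    "LPE":  {"HET_vs_WT": "*",   "KO_vs_WT": ""},
    "PC":   {"HET_vs_WT": "***", "KO_vs_WT": "***"},
    "PE":   {"HET_vs_WT": "*",   "KO_vs_WT": ""},
    "PG":   {"HET_vs_WT": "",    "KO_vs_WT": ""},
    "PI":   {"HET_vs_WT": "",    "KO_vs_WT": "*"},
    "PS":   {"HET_vs_WT": "",    "KO_vs_WT": ""},
    "SM":   {"HET_vs_WT": "*",   "KO_vs_WT": ""},
    "TG":   {"HET_vs_WT": "*",   "KO_vs_WT": "*"},
}

#: Raw echocardiography / necropsy fields simulated per animal.
ECHO_FIELDS = (
    "heart_rate",      # bpm
    "lvid_s", "lvid_d",    # LV internal diameter, systole/diastole, mm
    "lvpw_s", "lvpw_d",    # LV posterior wall thickness, mm
    "lvaw_s", "lvaw_d",    # LV anterior wall thickness, mm
    "lv_vol_s", "lv_vol_d",  # LV volume, ul
    "mv_e", "mv_a",        # mitral inflow early/atrial peak velocity, mm/s
    "body_weight",     # g
    "heart_weight",    # mg
)

#: Per-genotype (mean, SD) presets for each raw echo field, matching the
#: group summaries of the emulated five-month cohort.  Mitral velocities are
#: in mm/s.  Body weight encodes the knockout's ~40% deficit; heart weight is
#: genotype-independent (hypertrophy shows up in the ratio, not the organ mass).
ECHO_GROUP_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "WT": {
        "heart_rate": (504.88, 44.90),
        "lvid_s": (2.56, 0.30), "lvid_d": (3.78, 0.22),
        "lvpw_s": (1.14, 0.15), "lvpw_d": (0.87, 0.10),
        "lvaw_s": (1.29, 0.18), "lvaw_d": (0.82, 0.14),
        "lv_vol_s": (24.14, 6.84), "lv_vol_d": (61.44, 8.82),
        "mv_e": (546.05, 72.17), "mv_a": (454.86, 75.05),
        "body_weight": (30.0, 2.5), "heart_weight": (150.0, 15.0),
    },
    "HET": {
        "heart_rate": (515.10, 60.00),
        "lvid_s": (2.52, 0.48), "lvid_d": (3.85, 0.47),
        "lvpw_s": (1.20, 0.26), "lvpw_d": (0.88, 0.16),
        "lvaw_s": (1.27, 0.12), "lvaw_d": (0.76, 0.10),
        "lv_vol_s": (24.14, 10.89), "lv_vol_d": (65.28, 18.48),
        "mv_e": (607.41, 77.31), "mv_a": (495.07, 86.35),
        "body_weight": (30.0, 2.5), "heart_weight": (150.0, 15.0),
    },
    "KO": {
        "heart_rate": (551.38, 47.80),
        "lvid_s": (1.92, 0.27), "lvid_d": (3.08, 0.20),
        "lvpw_s": (1.11, 0.05), "lvpw_d": (0.87, 0.09),
        "lvaw_s": (1.09, 0.04), "lvaw_d": (0.71, 0.02),
        "lv_vol_s": (11.73, 4.35), "lv_vol_d": (37.61, 5.85),
        "mv_e": (543.06, 63.45), "mv_a": (413.80, 38.67),
        "body_weight": (18.0, 1.8), "heart_weight": (150.0, 15.0),
    },
}

#: Cohort sizes of the emulated echo study.
ECHO_GROUP_N = {"WT": 5, "HET": 9, "KO": 3}

#: Reference LV-mass group means of the emulated cohort:
#: genotype -> (uncorrected mg, corrected mg).  The corrected column is the
#: uncorrected cube-formula mass times the standard 0.8 correction factor;
#: kept as validation presets for that identity.
REFERENCE_LV_MASS: dict[str, tuple[float, float]] = {
    "WT": (115.58, 92.47),
    "HET": (113.66, 90.93),
    "KO": (75.07, 60.06),
}

#: Reference derived stroke volumes (ul) of the emulated cohort group means.
REFERENCE_STROKE_VOLUME = {"WT": 37.3, "HET": 41.14, "KO": 25.88}
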