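"""Published cohort summaries of the modeled breast-VMAT study (inputs).

These are the printed group counts (clinical covariates by dermatitis
outcome) and mean +/- SD summaries (skin and PTV dose-volume parameters by
outcome) for the 148-patient cohort: 99 without and 49 with grade >= 2
radiation dermatitis.  They serve two roles: reference marginals for the
synthetic cohort generator, and inputs to the cohort-statistics report
(`dosederm stats`) that recomputes the group-comparison tests.
"""

from __future__ import annotations

from dosederm.metrics import SummaryPair, chi_square_2xk, pooled_t_from_summary

N_TOTAL = 148
N_NO_RD = 99
N_RD = 49
PREVALENCE = N_RD / N_TOTAL  # 0.331

AGE_MEAN = {"total": 56.0, "no_rd": 55.0, "rd": 59.0}
BMI_MEAN = {"total": 24.73, "no_rd": 24.46, "rd": 25.29}

# Categorical covariates: {level: (count without RD, count with RD)}
TABLE1_COUNTS = {
    "laterality": {"left": (44, 26), "right": (55, 23)},
    "surgery": {"TM/MRM": (19, 10), "BCS": (80, 39)},
    "ajcc_stage": {0: (24, 10), 1: (31, 15), 2: (32, 16), 3: (11, 6), 4: (1, 2)},
    "scf": {False: (78, 32), True: (21, 17)},
    "imn": {False: (82, 33), True: (17, 16)},
    "chemotherapy": {False: (51, 23), True: (48, 26)},
}

# DVH parameters, cc: (total mean, total SD, no-RD mean, no-RD SD, RD mean, RD SD)
TABLE2_SUMMARIES = {
    "skin5mm_V5Gy": (325.0, 120.9, 312.7, 123.6, 349.9, 112.3),
    "skin5mm_V10Gy": (258.1, 89.3, 248.6, 90.9, 277.2, 83.7),
    "skin5mm_V15Gy": (225.9, 74.0, 218.0, 76.3, 241.8, 67.0),
    "skin5mm_V20Gy": (204.9, 62.2, 198.2, 63.8, 218.3, 57.1),
    "skin5mm_V25Gy": (187.4, 53.8, 181.26, 55.1, 199.8, 49.4),
    "skin5mm_V30Gy": (171.8, 46.8, 166.5, 47.8, 182.5, 43.4),
    "skin5mm_V35Gy": (156.9, 41.0, 152.3, 41.8, 166.1, 38.2),
    "skin5mm_V40Gy": (141.4, 36.6, 137.5, 37.3, 149.3, 37.1),
    "skin5mm_V45Gy": (118.2, 31.1, 114.6, 31.1, 125.4, 30.1),
    "skin5mm_V50Gy": (47.6, 24.6, 46.3, 24.8, 50.2, 24.2),
    "ptv100": (703.1, 387.6, 648.0, 374.3, 814.5, 394.1),
    "ptv105": (69.2, 133.7, 57.2, 80.0, 93.5, 202.1),
}


def clinical_comparison_report() -> dict:
    """Chi-square group comparisons recomputed from the printed counts."""
    report = {}
    for name, levels in TABLE1_COUNTS.items():
        table = [list(counts) for counts in levels.values()]
        # rows = levels, columns = (without RD, with RD); test as 2xk on the
        # transposed orientation (equivalent chi-square).
        chi2, df, p = chi_square_2xk(table)
        report[name] = {"chi2": chi2, "df": df, "p": p}
    return report


def dvh_comparison_report() -> dict:
    """Pooled-t group comparisons recomputed from the printed summaries."""
    report = {}
    for name, (_, _, m0, s0, m1, s1) in TABLE2_SUMMARIES.items():
        t, df, p = pooled_t_from_summary(
            SummaryPair(m0, s0, N_NO_RD), SummaryPair(m1, s1, N_RD)
        )
        report[name] = {"t": t, "df": df, "p": p}
    return report
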